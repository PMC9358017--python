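"""SNP classification and the fS observed/expected polymorphism statistic.

Given a codon-aligned multi-strain alignment and a designated reference
record, every single-base difference from the reference is classified as
synonymous / missense / nonsense and transition / transversion.  Counts
are then aggregated by reference codon identity: if a codon type collected
``So`` synonymous and ``NSo`` non-synonymous polymorphisms and ``s9`` of
its nine single-base neighbors are synonymous, the expected synonymous
count under equal substitution rates is ``Se = s9/9 * (So + NSo)`` and

    fS = So / Se

so fS = 1 means synonymous changes occur exactly as often as an
equal-rate process predicts.  Because synonymous changes in two-fold
degenerate codons are pure transitions, a transition excess of kappa
drives their fS toward 3*kappa/(kappa+2) while four-fold codons stay
near 1 — the degeneracy-class contrast this statistic exists to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genetic_code as gc


class AlignmentError(ValueError):
    """Records of unequal length, missing reference, or broken frame."""


@dataclass(frozen=True)
class SNPRecord:
    """One distinct non-reference allele at one alignment column."""

    gene_id: str
    codon_index: int  # 1-based codon number in the alignment
    codon_position: int  # 1, 2 or 3 within the codon
    ref_base: str
    alt_base: str
    ref_codon: str
    alt_codon: str
    effect: str
    is_transition: bool
    allele_count: int  # number of strains carrying this allele


def _as_records(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, Mapping):
        return list(alignment.items())
    return list(alignment)


def extract_snps(
    alignment: Sequence[tuple[str, str]] | Mapping[str, str],
    reference_id: str,
    gene_id: str = "",
) -> list[SNPRecord]:
    """Classify every distinct single-base allele against the reference.

    The alignment is a sequence of ``(id, sequence)`` pairs (or a mapping);
    all sequences must be equal length and in frame.  Reference codons with
    gaps/ambiguity, or that are stop codons, skip the whole column; a
    non-reference codon with gaps/ambiguity, or differing from the
    reference at more than one position (not a single-base change), skips
    only that strain's observation.  One record is emitted per distinct
    (codon, position, alt base) allele with its carrier count.
    """
    records = _as_records(alignment)
    if not records:
        raise AlignmentError("alignment contains no records")
    seqs = {rid: seq.upper().replace("U", "T") for rid, seq in records}
    if reference_id not in seqs:
        raise AlignmentError(f"reference id {reference_id!r} not found in alignment")
    ref = seqs[reference_id]
    if len(ref) % 3 != 0:
        raise AlignmentError(
            f"alignment length {len(ref)} is not divisible by 3"
        )
    for rid, seq in seqs.items():
        if len(seq) != len(ref):
            raise AlignmentError(
                f"record {rid!r} has length {len(seq)}, expected {len(ref)}"
            )
    others = [(rid, seq) for rid, seq in records if rid != reference_id]

    counts: dict[tuple[int, int, str], int] = {}
    for ci in range(len(ref) // 3):
        ref_codon = ref[3 * ci : 3 * ci + 3]
        if any(b not in gc.BASES for b in ref_codon) or ref_codon in gc.STOP_CODONS:
            continue
        for _, seq in others:
            codon = seq[3 * ci : 3 * ci + 3]
            if any(b not in gc.BASES for b in codon):
                continue
            diffs = [p for p in range(3) if codon[p] != ref_codon[p]]
            if len(diffs) != 1:
                continue  # identical, or multi-hit codon (not a single SNP)
            pos = diffs[0]
            key = (ci, pos, codon[pos])
            counts[key] = counts.get(key, 0) + 1

    snps = []
    for (ci, pos, alt), n in sorted(counts.items()):
        ref_codon = ref[3 * ci : 3 * ci + 3]
        sub = gc.classify_substitution(ref_codon, pos + 1, alt)
        snps.append(
            SNPRecord(
                gene_id=gene_id,
                codon_index=ci + 1,
                codon_position=pos + 1,
                ref_base=ref_codon[pos],
                alt_base=alt,
                ref_codon=ref_codon,
                alt_codon=sub.target,
                effect=sub.effect,
                is_transition=sub.is_transition,
                allele_count=n,
            )
        )
    return snps


def codon_fs_summary(
    snps: Iterable[SNPRecord], *, count: str = "alleles"
) -> pd.DataFrame:
    """Aggregate SNPs by reference codon identity and compute fS.

    One row per sense codon (61 rows; ATG and TGG have s9 = 0, hence
    Se = 0 and fS = NaN, leaving the 59 codons the statistic is defined
    for).  ``count='alleles'`` counts each distinct allele once (default,
    invariant to strain sampling depth); ``count='strains'`` weights each
    allele by its carrier count.
    """
    if count not in ("alleles", "strains"):
        raise ValueError(f"count must be 'alleles' or 'strains', got {count!r}")
    so: dict[str, float] = {c: 0.0 for c in gc.SENSE_CODONS}
    nso: dict[str, float] = {c: 0.0 for c in gc.SENSE_CODONS}
    for snp in snps:
        w = 1.0 if count == "alleles" else float(snp.allele_count)
        if snp.effect == gc.SYNONYMOUS:
            so[snp.ref_codon] += w
        else:
            nso[snp.ref_codon] += w

    rows = []
    for codon in gc.SENSE_CODONS:
        prof = gc.substitution_profile(codon)
        s9 = prof.s9
        total = so[codon] + nso[codon]
        se = s9 / 9.0 * total
        nse = (9 - s9) / 9.0 * total
        if s9 == 0:
            fs = math.nan
        elif se == 0:
            fs = 0.0
        else:
            fs = so[codon] / se
        rows.append(
            {
                "codon": codon,
                "amino_acid": gc.translate(codon),
                "degeneracy_class": gc.degeneracy_class(codon),
                "s9": s9,
                "So": so[codon],
                "NSo": nso[codon],
                "Se": se,
                "NSe": nse,
                "fS": fs,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassComparison:
    """Per-degeneracy-class fS summaries and the TFD-vs-FFD rank-sum test."""

    by_class: pd.DataFrame
    u_statistic: float | None
    p_value: float | None
    n_twofold: int
    n_fourfold: int


_COMPARED_CLASSES = (gc.TWOFOLD, gc.FOURFOLD, gc.SIXFOLD_FAMILY, gc.SIXFOLD_SPLIT)


def class_comparison(summary: pd.DataFrame) -> ClassComparison:
    """Summarize fS by degeneracy class and compare TFD vs FFD.

    Only codons with at least one observed polymorphism and a defined fS
    enter the summaries.  The two-sided Mann-Whitney U test uses the
    normal approximation with tie correction (no continuity correction, so
    identical samples give p = 1).  U and p are ``None`` when either
    compared class has fewer than 2 usable codons.
    """
    usable = summary[(summary["So"] + summary["NSo"] > 0) & summary["fS"].notna()]
    rows = []
    values: dict[str, np.ndarray] = {}
    for label in _COMPARED_CLASSES:
        vals = usable.loc[usable["degeneracy_class"] == label, "fS"].to_numpy(float)
        values[label] = vals
        rows.append(
            {
                "degeneracy_class": label,
                "n": len(vals),
                "mean_fS": float(np.mean(vals)) if len(vals) else math.nan,
                "median_fS": float(np.median(vals)) if len(vals) else math.nan,
                "min_fS": float(np.min(vals)) if len(vals) else math.nan,
                "max_fS": float(np.max(vals)) if len(vals) else math.nan,
            }
        )
    tfd, ffd = values[gc.TWOFOLD], values[gc.FOURFOLD]
    u = p = None
    if len(tfd) >= 2 and len(ffd) >= 2:
        res = stats.mannwhitneyu(
            tfd, ffd, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        u, p = float(res.statistic), float(res.pvalue)
    return ClassComparison(
        by_class=pd.DataFrame(rows),
        u_statistic=u,
        p_value=p,
        n_twofold=len(tfd),
        n_fourfold=len(ffd),
    )
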