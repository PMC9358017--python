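"""Pairwise gene dN/dS from single-position codon differences.

The counting scheme deliberately stays simple: two codon-aligned,
equal-length coding sequences are compared codon by codon, pairs differing
at exactly one position are classified synonymous or non-synonymous by
translation, and pairs differing at two or three positions are excluded
(their count is reported so the information loss is visible).  Sites come
from :mod:`codonsites.sites` under either the equal-rate ("old") or the
kappa-weighted, nonsense-corrected ("modified") model, averaged between the
two sequences by default.

No multiple-hit correction is applied by default; an optional Jukes-Cantor
transform (d = -3/4 ln(1 - 4p/3)) is available for both pS and pN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from . import genetic_code as gc
from .sites import MODIFIED, OLD, codon_sites

_AMBIG_SKIP = "skip"
_STOP_ERROR = "error"


class FrameError(ValueError):
    """Sequence length not divisible by 3, or frame otherwise broken."""


class InternalStopError(ValueError):
    """An in-frame stop codon occurs before the end of the sequence."""


def _normalize_cds(seq: str, seq_id: str = "") -> str:
    norm = seq.upper().replace("U", "T")
    if len(norm) % 3 != 0:
        label = f" in record {seq_id!r}" if seq_id else ""
        raise FrameError(
            f"sequence length {len(norm)}{label} is not divisible by 3"
        )
    return norm


def _codon_ok(codon: str) -> bool:
    return all(b in gc.BASES for b in codon)


@dataclass(frozen=True)
class GeneSites:
    """Summed site values of one coding sequence."""

    seq_id: str
    method: str
    kappa: float | None
    S_total: float
    N_total: float
    n_codons_counted: int
    n_codons_skipped: int


def gene_sites(
    cds: str,
    method: str = MODIFIED,
    kappa: float = 4.0,
    *,
    on_internal_stop: str = _STOP_ERROR,
    skip_start: bool = False,
    seq_id: str = "",
) -> GeneSites:
    """Sum per-codon S and NS site values over an in-frame CDS.

    A terminal stop codon is stripped; an internal stop raises
    :class:`InternalStopError` unless ``on_internal_stop='skip'``.  Codons
    containing non-ACGT characters are skipped and counted.  With
    ``skip_start`` the first codon is excluded from the sums (useful when
    the initiation codon should not contribute sites).
    """
    norm = _normalize_cds(cds, seq_id)
    codons = list(gc.iter_codons(norm))
    if codons and _codon_ok(codons[-1]) and codons[-1] in gc.STOP_CODONS:
        codons = codons[:-1]
    if skip_start and codons:
        codons = codons[1:]
    s_total = 0.0
    n_total = 0.0
    counted = 0
    skipped = 0
    for i, codon in enumerate(codons):
        if not _codon_ok(codon):
            skipped += 1
            continue
        if codon in gc.STOP_CODONS:
            if on_internal_stop == _AMBIG_SKIP:
                skipped += 1
                continue
            raise InternalStopError(
                f"internal stop codon {codon} at codon {i + 1}"
                + (f" of record {seq_id!r}" if seq_id else "")
            )
        sv = codon_sites(codon, method, kappa)
        s_total += float(sv.S)
        n_total += float(sv.NS)
        counted += 1
    return GeneSites(
        seq_id=seq_id,
        method=method,
        kappa=kappa if method == MODIFIED else None,
        S_total=s_total,
        N_total=n_total,
        n_codons_counted=counted,
        n_codons_skipped=skipped,
    )


@dataclass(frozen=True)
class DiffCounts:
    """Codon-pair difference tallies between two aligned sequences."""

    sd: int
    nd: int
    n_single: int
    n_multi: int
    n_identical: int
    n_excluded: int


def count_differences(cds_a: str, cds_b: str) -> DiffCounts:
    """Count synonymous/non-synonymous single-position codon differences.

    Codon pairs differing at >=2 positions are excluded from Sd/Nd (no
    substitution-pathway averaging) and reported in ``n_multi``; pairs
    where either codon is a stop or contains ambiguity are excluded and
    reported in ``n_excluded``.
    """
    a = _normalize_cds(cds_a)
    b = _normalize_cds(cds_b)
    if len(a) != len(b):
        raise FrameError(
            f"sequences have different lengths ({len(a)} vs {len(b)}); "
            "alignment without indels is required"
        )
    sd = nd = n_single = n_multi = n_identical = n_excluded = 0
    for ca, cb in zip(gc.iter_codons(a), gc.iter_codons(b)):
        if not (_codon_ok(ca) and _codon_ok(cb)):
            n_excluded += 1
            continue
        if ca in gc.STOP_CODONS or cb in gc.STOP_CODONS:
            n_excluded += 1
            continue
        ndiff = sum(x != y for x, y in zip(ca, cb))
        if ndiff == 0:
            n_identical += 1
        elif ndiff == 1:
            n_single += 1
            if gc.translate(ca) == gc.translate(cb):
                sd += 1
            else:
                nd += 1
        else:
            n_multi += 1
    return DiffCounts(sd, nd, n_single, n_multi, n_identical, n_excluded)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DnDsResult:
    """dN/dS of one gene pair under one site model.

    ``ratio`` is ``None`` when undefined (no synonymous differences or no
    sites); ``undefined_reason`` then carries a machine-readable flag.
    """

    id_a: str
    id_b: str
    method: str
    kappa: float | None
    sd: int
    nd: int
    s_sites: float
    n_sites: float
    ps: float | None
    pn: float | None
    ratio: float | None
    undefined_reason: str | None
    n_single: int
    n_multi: int
    n_identical: int
    n_excluded: int


def dnds_pair(
    cds_a: str,
    cds_b: str,
    method: str = MODIFIED,
    kappa: float = 4.0,
    *,
    sites: str = "mean",
    jc_correction: bool = False,
    ids: tuple[str, str] = ("seq_a", "seq_b"),
    on_internal_stop: str = _STOP_ERROR,
    skip_start: bool = False,
) -> DnDsResult:
    """dN/dS between two equal-length in-frame sequences.

    ``sites='mean'`` averages S/N site totals over the two sequences (the
    usual pairwise convention); ``sites='first'`` uses the first sequence
    as the reference.  An undefined ratio is flagged, never silently zero.
    """
    if sites not in ("mean", "first"):
        raise ValueError(f"sites must be 'mean' or 'first', got {sites!r}")
    diffs = count_differences(cds_a, cds_b)
    gs_a = gene_sites(
        cds_a, method, kappa, on_internal_stop=on_internal_stop,
        skip_start=skip_start, seq_id=ids[0],
    )
    if sites == "mean":
        gs_b = gene_sites(
            cds_b, method, kappa, on_internal_stop=on_internal_stop,
            skip_start=skip_start, seq_id=ids[1],
        )
        s_sites = (gs_a.S_total + gs_b.S_total) / 2.0
        n_sites = (gs_a.N_total + gs_b.N_total) / 2.0
    else:
        s_sites = gs_a.S_total
        n_sites = gs_a.N_total

    ps = pn = ratio = None
    reason = None
    if s_sites <= 0 or n_sites <= 0:
        reason = "no_sites"
    else:
        ps = diffs.sd / s_sites
        pn = diffs.nd / n_sites
        if jc_correction:
            ps = _jukes_cantor(ps)
            pn = _jukes_cantor(pn)
        if diffs.sd == 0 or not math.isfinite(ps) or ps == 0:
            reason = "no_synonymous_differences" if diffs.sd == 0 else "saturated"
        else:
            ratio = pn / ps
    return DnDsResult(
        id_a=ids[0],
        id_b=ids[1],
        method=method,
        kappa=kappa if method == MODIFIED else None,
        sd=diffs.sd,
        nd=diffs.nd,
        s_sites=s_sites,
        n_sites=n_sites,
        ps=ps,
        pn=pn,
        ratio=ratio,
        undefined_reason=reason,
        n_single=diffs.n_single,
        n_multi=diffs.n_multi,
        n_identical=diffs.n_identical,
        n_excluded=diffs.n_excluded,
    )


@dataclass(frozen=True)
class GeneComposition:
    """Codon-degeneracy covariates of one gene."""

    n_tfd: int
    n_ffd: int
    tfd_ffd_ratio: float | None
    n_pretermination: int
    n_sense: int
    pretermination_fraction: float | None


def gene_composition(cds: str) -> GeneComposition:
    """TFD/FFD codon counts and the pretermination-codon fraction.

    TFD counts codons of the nine two-fold degenerate amino acids; FFD
    counts codons of Val/Pro/Thr/Ala/Gly (family boxes of six-fold amino
    acids are not included in either).  A terminal stop is ignored.
    """
    norm = _normalize_cds(cds)
    n_tfd = n_ffd = n_pre = n_sense = 0
    codons = list(gc.iter_codons(norm))
    if codons and _codon_ok(codons[-1]) and codons[-1] in gc.STOP_CODONS:
        codons = codons[:-1]
    for codon in codons:
        if not _codon_ok(codon) or codon in gc.STOP_CODONS:
            continue
        n_sense += 1
        label = gc.degeneracy_class(codon)
        if label == gc.TWOFOLD:
            n_tfd += 1
        elif label == gc.FOURFOLD:
            n_ffd += 1
        if gc.is_pretermination(codon):
            n_pre += 1
    return GeneComposition(
        n_tfd=n_tfd,
        n_ffd=n_ffd,
        tfd_ffd_ratio=(n_tfd / n_ffd) if n_ffd else None,
        n_pretermination=n_pre,
        n_sense=n_sense,
        pretermination_fraction=(n_pre / n_sense) if n_sense else None,
    )


@dataclass
class MethodComparison:
    """Old vs modified dN/dS across a set of gene pairs.

    ``per_gene`` has one row per pair: ids, both ratios, percent increase,
    and the TFD:FFD / pretermination covariates of the first sequence.
    Correlations are Pearson product-moment over genes where both ratios
    and the covariate are defined; ``None`` with fewer than 3 usable genes.
    """

    per_gene: pd.DataFrame
    kappa: float
    r_tfd_ffd: float | None = None
    p_tfd_ffd: float | None = None
    r_pretermination: float | None = None
    p_pretermination: float | None = None
    n_usable: int = 0


def compare_methods(
    gene_pairs: Iterable[tuple[str, str, str]],
    kappa: float = 4.0,
    **dnds_kwargs,
) -> MethodComparison:
    """Score each (gene_id, cds_a, cds_b) with both site models.

    percent_increase = 100*(dnds_modified - dnds_old)/dnds_old, defined only
    where both ratios are defined and the old ratio is positive.
    """
    rows = []
    for gene_id, cds_a, cds_b in gene_pairs:
        old = dnds_pair(cds_a, cds_b, OLD, kappa, ids=(gene_id, gene_id), **dnds_kwargs)
        new = dnds_pair(cds_a, cds_b, MODIFIED, kappa, ids=(gene_id, gene_id), **dnds_kwargs)
        comp = gene_composition(cds_a)
        increase = None
        if old.ratio is not None and new.ratio is not None and old.ratio > 0:
            increase = 100.0 * (new.ratio - old.ratio) / old.ratio
        rows.append(
            {
                "gene_id": gene_id,
                "dnds_old": old.ratio,
                "dnds_modified": new.ratio,
                "percent_increase": increase,
                "tfd_ffd_ratio": comp.tfd_ffd_ratio,
                "pretermination_fraction": comp.pretermination_fraction,
                "sd": new.sd,
                "nd": new.nd,
                "n_multi": new.n_multi,
            }
        )
    per_gene = pd.DataFrame(rows)
    result = MethodComparison(per_gene=per_gene, kappa=kappa)
    if len(per_gene):
        for covariate, (r_attr, p_attr) in {
            "tfd_ffd_ratio": ("r_tfd_ffd", "p_tfd_ffd"),
            "pretermination_fraction": ("r_pretermination", "p_pretermination"),
        }.items():
            usable = per_gene.dropna(subset=["percent_increase", covariate])
            if len(usable) >= 3 and usable[covariate].nunique() > 1:
                r, p = stats.pearsonr(usable["percent_increase"], usable[covariate])
                setattr(result, r_attr, float(r))
                setattr(result, p_attr, float(p))
        result.n_usable = int(per_gene["percent_increase"].notna().sum())
    return result
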