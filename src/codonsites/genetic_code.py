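"""Genetic-code machinery for site counting.

Everything downstream (site values, dN/dS, fS) reduces to classifying the
nine single-base neighbors of a sense codon as synonymous / missense /
nonsense and as transition / transversion.  This module owns that
classification, the codon degeneracy classes, and the enumeration of
pretermination codons (sense codons one substitution away from a stop).

Codons are plain 3-letter DNA strings internally; RNA (``U``) and lowercase
input are normalized on entry.  The code table is loaded from a packaged
plain-text file so alternative tables could be dropped in, but the standard
code (translation table 1) is the default and the only one exercised here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterator

BASES: tuple[str, ...] = ("A", "C", "G", "T")

#: transition partner of each base (purine<->purine, pyrimidine<->pyrimidine)
_TI_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"

ONEFOLD = "onefold"
TWOFOLD = "twofold"
THREEFOLD = "threefold"
FOURFOLD = "fourfold"
SIXFOLD_FAMILY = "sixfold_family"
SIXFOLD_SPLIT = "sixfold_split"

DEGENERACY_LABELS = (
    ONEFOLD,
    TWOFOLD,
    THREEFOLD,
    FOURFOLD,
    SIXFOLD_FAMILY,
    SIXFOLD_SPLIT,
)


class CodonError(ValueError):
    """Invalid codon input (wrong length, non-nucleotide characters)."""


class StopCodonError(CodonError):
    """A stop codon was supplied where a sense codon is required."""


def _load_code_table(name: str = "standard_code.tsv") -> dict[str, str]:
    text = (resources.files(__package__) / "data" / name).read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split("\t")
        table[codon] = aa
    if len(table) != 64:
        raise ValueError(f"code table {name!r} has {len(table)} codons, expected 64")
    return table


#: codon -> one-letter amino acid, ``*`` for stop (standard code)
CODON_TABLE: dict[str, str] = _load_code_table()

STOP_CODONS: frozenset[str] = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
)


def normalize_codon(codon: str) -> str:
    """Return the canonical DNA form of *codon* (uppercase, U->T).

    Raises :class:`CodonError` for anything that is not three A/C/G/T/U
    letters after case folding.
    """
    if not isinstance(codon, str):
        raise CodonError(f"codon must be a string, got {type(codon).__name__}")
    norm = codon.upper().replace("U", "T")
    if len(norm) != 3:
        raise CodonError(f"codon {codon!r} does not have length 3")
    for base in norm:
        if base not in BASES:
            raise CodonError(f"codon {codon!r} contains non-ACGT(U) base {base!r}")
    return norm


def _require_sense(codon: str) -> str:
    norm = normalize_codon(codon)
    if norm in STOP_CODONS:
        raise StopCodonError(f"{codon!r} is a stop codon, not a sense codon")
    return norm


def translate(codon: str) -> str:
    """One-letter amino acid for *codon*; ``*`` for a stop codon."""
    return CODON_TABLE[normalize_codon(codon)]


def is_stop(codon: str) -> bool:
    return normalize_codon(codon) in STOP_CODONS


def is_transition(base_a: str, base_b: str) -> bool:
    """True iff *base_a* -> *base_b* is a transition (A<->G or C<->T)."""
    return _TI_PARTNER[base_a] == base_b


@dataclass(frozen=True)
class SingleSubstitution:
    """One single-base change in a codon.

    ``position`` is 1-based (first/second/third codon position).
    ``effect`` is ``synonymous``, ``missense`` or ``nonsense``.
    """

    source: str
    position: int
    alt_base: str
    target: str
    is_transition: bool
    effect: str


@dataclass(frozen=True)
class SubstitutionProfile:
    """Counts of a sense codon's nine neighbors by class.

    ``nti``/``ntv`` count all non-synonymous changes, nonsense included (the
    equal-rate method treats them together); ``nti_stop``/``ntv_stop`` count
    the subset landing on stop codons, which the modified method removes.
    """

    codon: str
    sti: int
    stv: int
    nti: int
    ntv: int
    nti_stop: int
    ntv_stop: int

    @property
    def s9(self) -> int:
        """Number of the nine neighbors that are synonymous (Sti + Stv)."""
        return self.sti + self.stv

    @property
    def n_stop(self) -> int:
        return self.nti_stop + self.ntv_stop


def classify_substitution(codon: str, position: int, alt_base: str) -> SingleSubstitution:
    """Classify the change of *codon* at 1-based *position* to *alt_base*."""
    source = _require_sense(codon)
    if position not in (1, 2, 3):
        raise CodonError(f"codon position must be 1, 2 or 3, got {position}")
    alt = normalize_codon("A" + alt_base + "A")[1] if len(alt_base) == 1 else ""
    if alt == "" or alt not in BASES:
        raise CodonError(f"invalid alternative base {alt_base!r}")
    ref_base = source[position - 1]
    if alt == ref_base:
        raise CodonError(
            f"alternative base {alt!r} equals the reference base at position "
            f"{position} of {source}"
        )
    target = source[: position - 1] + alt + source[position:]
    if target in STOP_CODONS:
        effect = NONSENSE
    elif CODON_TABLE[target] == CODON_TABLE[source]:
        effect = SYNONYMOUS
    else:
        effect = MISSENSE
    return SingleSubstitution(
        source=source,
        position=position,
        alt_base=alt,
        target=target,
        is_transition=is_transition(ref_base, alt),
        effect=effect,
    )


@lru_cache(maxsize=None)
def enumerate_neighbors(codon: str) -> tuple[SingleSubstitution, ...]:
    """The nine single-base neighbors of a sense codon, in fixed order.

    Ordering is position 1->3, alternative base A<C<G<T, so downstream
    output is byte-stable.  Exactly 3 of the 9 are transitions.
    """
    source = _require_sense(codon)
    subs = []
    for position in (1, 2, 3):
        ref_base = source[position - 1]
        for alt in BASES:
            if alt != ref_base:
                subs.append(classify_substitution(source, position, alt))
    return tuple(subs)


@lru_cache(maxsize=None)
def substitution_profile(codon: str) -> SubstitutionProfile:
    """Tally the nine neighbors of a sense codon into the six class counts."""
    source = _require_sense(codon)
    sti = stv = nti = ntv = nti_stop = ntv_stop = 0
    for sub in enumerate_neighbors(source):
        if sub.effect == SYNONYMOUS:
            if sub.is_transition:
                sti += 1
            else:
                stv += 1
        else:
            if sub.is_transition:
                nti += 1
                if sub.effect == NONSENSE:
                    nti_stop += 1
            else:
                ntv += 1
                if sub.effect == NONSENSE:
                    ntv_stop += 1
    return SubstitutionProfile(source, sti, stv, nti, ntv, nti_stop, ntv_stop)


@lru_cache(maxsize=1)
def pretermination_set() -> frozenset[str]:
    """Sense codons with at least one nonsense single-base neighbor.

    Under the standard code there are 18 such codons carrying 23 nonsense
    substitutions in total; five codons (TTA, TCA, TGG, TAT, TAC) have two.
    """
    return frozenset(
        c for c in SENSE_CODONS if substitution_profile(c).n_stop >= 1
    )


def is_pretermination(codon: str) -> bool:
    return _require_sense(codon) in pretermination_set()


def nonsense_substitution_count() -> int:
    """Total number of sense->stop single-base substitutions in the code."""
    return sum(substitution_profile(c).n_stop for c in SENSE_CODONS)


# Degeneracy classes.  Twofold covers the nine amino acids whose two codons
# interconvert only by a third-position transition; fourfold the five family
# boxes Val/Pro/Thr/Ala/Gly; the sixfold amino acids Leu/Arg/Ser are split
# into their family box (CTN/CGN/TCN) and split box (TTR/AGR/AGY) halves,
# which behave like fourfold and twofold codons respectively.
_ONEFOLD = frozenset({"ATG", "TGG"})
_THREEFOLD = frozenset({"ATT", "ATC", "ATA"})
_SIXFOLD_FAMILY = frozenset(
    {p + b for p in ("CT", "CG", "TC") for b in BASES}
)
_SIXFOLD_SPLIT = frozenset({"TTA", "TTG", "AGA", "AGG", "AGT", "AGC"})
_FOURFOLD = frozenset(
    {p + b for p in ("GT", "CC", "AC", "GC", "GG") for b in BASES}
)
_TWOFOLD = frozenset(SENSE_CODONS) - _ONEFOLD - _THREEFOLD - _SIXFOLD_FAMILY - _SIXFOLD_SPLIT - _FOURFOLD


def degeneracy_class(codon: str) -> str:
    """Degeneracy label of a sense codon (see :data:`DEGENERACY_LABELS`)."""
    norm = _require_sense(codon)
    if norm in _ONEFOLD:
        return ONEFOLD
    if norm in _THREEFOLD:
        return THREEFOLD
    if norm in _SIXFOLD_FAMILY:
        return SIXFOLD_FAMILY
    if norm in _SIXFOLD_SPLIT:
        return SIXFOLD_SPLIT
    if norm in _FOURFOLD:
        return FOURFOLD
    return TWOFOLD


def iter_codons(sequence: str) -> Iterator[str]:
    """Yield consecutive triplets of *sequence* (no normalization)."""
    for i in range(0, len(sequence) - len(sequence) % 3, 3):
        yield sequence[i : i + 3]
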