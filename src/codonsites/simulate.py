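"""Codon-sequence substitution simulator with a kappa:1 Ti:Tv process.

Emulates a star-shaped strain panel: independent descendants of one
reference sequence, each carrying a fixed number of accepted single-base
substitutions.  Per accepted event a codon and one of its nine neighbors
are drawn — each transition neighbor with relative rate ``kappa``, each
transversion with rate 1 — and the change is accepted with probability 1
if synonymous, ``omega`` if missense, and 0 if nonsense (when nonsense
rejection is on, the default; nonsense changes are treated as lethal).
Rejected events redraw both the codon and the substitution, so accepted
events land on codons in proportion to their total accepted substitution
weight — which is what makes the neutral (omega = 1) process calibrate to
dN/dS = 1 under the kappa-matched modified site model.

All randomness flows through one :class:`numpy.random.Generator` seeded
explicitly, so runs are reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import genetic_code as gc
from .polymorphism import SNPRecord, extract_snps


class SimulationError(RuntimeError):
    """The rejection sampler could not accept an event within the cap."""


_MAX_ATTEMPTS = 10_000

_INFORMATIVE_CLASSES = (gc.FOURFOLD, gc.SIXFOLD_FAMILY)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated strain panel.

    Exactly one of ``reference`` (an in-frame sense-codon sequence) or
    ``n_codons`` (length of a randomly drawn reference) must be given.
    ``substitutions_per_sequence`` is the number of *accepted* events per
    descendant.  ``codon_weights`` optionally biases the random reference's
    codon usage (mapping codon -> relative weight over sense codons).
    """

    n_sequences: int
    substitutions_per_sequence: int
    kappa: float = 4.0
    omega: float = 1.0
    reject_nonsense: bool = True
    seed: int = 0
    reference: str | None = None
    n_codons: int | None = None
    codon_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.substitutions_per_sequence < 0:
            raise ValueError("substitutions_per_sequence must be >= 0")
        if not (self.kappa > 0):
            raise ValueError(f"kappa must be positive, got {self.kappa!r}")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError(f"omega must be in [0, 1], got {self.omega!r}")
        if (self.reference is None) == (self.n_codons is None):
            raise ValueError("give exactly one of reference or n_codons")
        if self.n_codons is not None and self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def random_reference(
    n_codons: int,
    rng: np.random.Generator,
    codon_weights: Mapping[str, float] | None = None,
) -> str:
    """Random in-frame sequence of sense codons.

    Codon usage is uniform over the 61 sense codons unless *codon_weights*
    supplies relative weights (codons absent from the mapping get weight 0).
    """
    codons = np.array(gc.SENSE_CODONS)
    if codon_weights is None:
        p = None
    else:
        w = np.array([float(codon_weights.get(c, 0.0)) for c in gc.SENSE_CODONS])
        if w.sum() <= 0:
            raise ValueError("codon_weights must give positive total weight")
        p = w / w.sum()
    return "".join(rng.choice(codons, size=n_codons, p=p))


def draw_substitution(
    codon: str, kappa: float, rng: np.random.Generator
) -> gc.SingleSubstitution:
    """Draw one of the nine neighbors with Ti weight kappa, Tv weight 1.

    Each transition neighbor has probability kappa/(3*kappa + 6), each
    transversion 1/(3*kappa + 6).
    """
    if not (kappa > 0):
        raise ValueError(f"kappa must be positive, got {kappa!r}")
    neighbors = gc.enumerate_neighbors(codon)
    weights = np.array([kappa if s.is_transition else 1.0 for s in neighbors])
    idx = rng.choice(9, p=weights / weights.sum())
    return neighbors[idx]


def _check_reference(reference: str) -> list[str]:
    seq = reference.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"reference length {len(seq)} is not divisible by 3")
    codons = list(gc.iter_codons(seq))
    for i, codon in enumerate(codons):
        if any(b not in gc.BASES for b in codon):
            raise ValueError(f"reference codon {i + 1} ({codon!r}) is not pure ACGT")
        if codon in gc.STOP_CODONS:
            raise ValueError(f"reference contains stop codon {codon} at codon {i + 1}")
    return codons


def evolve_sequence(
    reference: str,
    n_substitutions: int,
    kappa: float = 4.0,
    omega: float = 1.0,
    reject_nonsense: bool = True,
    rng: np.random.Generator | None = None,
    max_attempts: int = _MAX_ATTEMPTS,
) -> str:
    """Apply *n_substitutions* accepted single-base changes to *reference*.

    Acceptance: synonymous 1, missense *omega*, nonsense 0 (or *omega* when
    ``reject_nonsense=False``).  A rejected event redraws codon and change;
    exceeding *max_attempts* rejections for one event raises
    :class:`SimulationError`.
    """
    if rng is None:
        rng = np.random.default_rng()
    codons = _check_reference(reference)
    n = len(codons)
    for _ in range(n_substitutions):
        for attempt in range(max_attempts):
            idx = int(rng.integers(n))
            codon = codons[idx]
            if codon in gc.STOP_CODONS:
                continue  # only reachable with reject_nonsense=False
            sub = draw_substitution(codon, kappa, rng)
            if sub.effect == gc.SYNONYMOUS:
                accept_p = 1.0
            elif sub.effect == gc.MISSENSE:
                accept_p = omega
            else:
                accept_p = 0.0 if reject_nonsense else omega
            if rng.random() < accept_p:
                codons[idx] = sub.target
                break
        else:
            raise SimulationError(
                f"no substitution accepted within {max_attempts} attempts "
                f"(omega={omega}, reject_nonsense={reject_nonsense})"
            )
    return "".join(codons)


def simulate_alignment(config: SimulationConfig) -> list[tuple[str, str]]:
    """Simulate a star alignment: the reference plus independent descendants.

    Returns ``[(id, sequence), ...]`` with the reference first (id
    ``reference``) and descendants ``strain_0001`` ... in order.  All
    records have equal length; with nonsense rejection on, no record ever
    contains a stop codon the reference did not.
    """
    rng = np.random.default_rng(config.seed)
    if config.reference is not None:
        reference = "".join(_check_reference(config.reference))
    else:
        reference = random_reference(config.n_codons, rng, config.codon_weights)
    records = [("reference", reference)]
    for i in range(1, config.n_sequences + 1):
        seq = evolve_sequence(
            reference,
            config.substitutions_per_sequence,
            kappa=config.kappa,
            omega=config.omega,
            reject_nonsense=config.reject_nonsense,
            rng=rng,
        )
        records.append((f"strain_{i:04d}", seq))
    return records


def simulate_pair(
    reference: str,
    n_substitutions: int,
    kappa: float = 4.0,
    omega: float = 1.0,
    reject_nonsense: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Two descendants of *reference* evolved independently (a divergent pair)."""
    if rng is None:
        rng = np.random.default_rng()
    a = evolve_sequence(reference, n_substitutions, kappa, omega, reject_nonsense, rng)
    b = evolve_sequence(reference, n_substitutions, kappa, omega, reject_nonsense, rng)
    return a, b


def kappa_from_snps(snps: Sequence[SNPRecord]) -> float | None:
    """Estimate kappa from synonymous third-position SNPs in family boxes.

    At the third position of a fourfold or family-box codon all three
    changes are synonymous — one transition and two transversions — so
    under a kappa:1 process the expected synonymous Ti:Tv count ratio at
    these sites is kappa:2 and ``kappa_hat = 2*Ti/Tv``.  Counts are
    weighted by carrier strains (allele_count), which keeps the per-event
    ratio exact.  Returns ``None`` when the Tv count is zero.
    """
    ti = tv = 0.0
    for snp in snps:
        if (
            snp.effect == gc.SYNONYMOUS
            and snp.codon_position == 3
            and gc.degeneracy_class(snp.ref_codon) in _INFORMATIVE_CLASSES
        ):
            if snp.is_transition:
                ti += snp.allele_count
            else:
                tv += snp.allele_count
    if tv == 0:
        return None
    return 2.0 * ti / tv


def estimate_kappa(
    alignment: Sequence[tuple[str, str]] | Mapping[str, str],
    reference_id: str,
) -> float | None:
    """Estimate the Ti:Tv rate ratio of an alignment (see kappa_from_snps)."""
    return kappa_from_snps(extract_snps(alignment, reference_id))
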