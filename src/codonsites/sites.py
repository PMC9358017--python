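"""Per-codon synonymous / non-synonymous site values.

Two site models over the nine single-base neighbors of a sense codon:

* ``old`` — the classic equal-rate count,
  ``S = (Sti + Stv) / 3``, ``NS = (Nti + Ntv) / 3``, so ``S + NS = 3``.

* ``modified`` — transitions weighted by the transition:transversion rate
  ratio kappa, and substitutions that create stop codons removed from the
  non-synonymous sites (nonsense changes are effectively lethal and do not
  contribute observable non-synonymous variation)::

      S  = (kappa*Sti + Stv) / (kappa + 2)
      NS = (kappa*(Nti - Nti') + (Ntv - Ntv')) / (kappa + 2)

  where the primed counts are the transitions/transversions landing on a
  stop codon.  For non-pretermination codons S + NS = 3 still holds; for
  pretermination codons the nonsense weight (kappa*Nti' + Ntv')/(kappa+2)
  is the shortfall.

Arithmetic is exact (``fractions.Fraction``) whenever kappa is an integer,
so regenerated tables are bit-stable; display rounding is half-away-from-
zero to 3 decimals (7/6 -> 1.167).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from numbers import Rational
from typing import Union

import pandas as pd

from . import genetic_code as gc

Number = Union[Fraction, float]

OLD = "old"
MODIFIED = "modified"
METHODS = (OLD, MODIFIED)


def round3(value: Number) -> float:
    """Round to 3 decimals, half away from zero (site values are >= 0)."""
    if isinstance(value, Rational):
        scaled = Fraction(value) * 1000
        sign = -1 if scaled < 0 else 1
        return sign * math.floor(abs(scaled) + Fraction(1, 2)) / 1000
    return float(Decimal(repr(float(value))).quantize(Decimal("0.001"), ROUND_HALF_UP))


def _as_exact(kappa: float) -> Number:
    """Integer-valued kappa becomes a Fraction so tables are exact."""
    if isinstance(kappa, Rational):
        return Fraction(kappa)
    if isinstance(kappa, float) and kappa.is_integer():
        return Fraction(int(kappa))
    return float(kappa)


def _check_kappa(kappa: float) -> None:
    if not (kappa > 0):
        raise ValueError(f"kappa must be positive, got {kappa!r}")


@dataclass(frozen=True)
class SiteValues:
    """S and NS site values of one codon under one method.

    ``S``/``NS`` are Fractions when exact arithmetic applies, floats
    otherwise; use :func:`round3` (or ``float()``) for display.
    """

    codon: str
    method: str
    kappa: float | None
    S: Number
    NS: Number

    @property
    def nonsense_weight(self) -> Number:
        """3 - S - NS: the site weight removed for nonsense substitutions."""
        return 3 - self.S - self.NS


def sites_old(codon: str) -> SiteValues:
    """Equal-rate site values: each of the nine changes counts 1/3 site."""
    prof = gc.substitution_profile(codon)
    return SiteValues(
        codon=prof.codon,
        method=OLD,
        kappa=None,
        S=Fraction(prof.sti + prof.stv, 3),
        NS=Fraction(prof.nti + prof.ntv, 3),
    )


def sites_modified(codon: str, kappa: float = 4.0) -> SiteValues:
    """Kappa-weighted, nonsense-corrected site values."""
    _check_kappa(kappa)
    prof = gc.substitution_profile(codon)
    k = _as_exact(kappa)
    denom = k + 2
    s = (k * prof.sti + prof.stv) / denom
    ns = (k * (prof.nti - prof.nti_stop) + (prof.ntv - prof.ntv_stop)) / denom
    return SiteValues(codon=prof.codon, method=MODIFIED, kappa=float(kappa), S=s, NS=ns)


def codon_sites(codon: str, method: str = MODIFIED, kappa: float = 4.0) -> SiteValues:
    """Dispatch to :func:`sites_old` or :func:`sites_modified`."""
    if method == OLD:
        return sites_old(codon)
    if method == MODIFIED:
        return sites_modified(codon, kappa)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def site_table(
    method: str = MODIFIED, kappa: float = 4.0, include_stops: bool = True
) -> pd.DataFrame:
    """Site values for all 61 sense codons as a DataFrame.

    Columns: codon, amino_acid, S, NS, degeneracy_class, is_pretermination.
    Stop-codon rows (S/NS = NaN) are appended when *include_stops* is true,
    mirroring the N/A cells of the printed genetic-code tables.  S and NS
    hold full-precision floats; round for display only.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == MODIFIED:
        _check_kappa(kappa)
    rows = []
    for codon in gc.SENSE_CODONS:
        sv = codon_sites(codon, method, kappa)
        rows.append(
            {
                "codon": codon,
                "amino_acid": gc.translate(codon),
                "S": float(sv.S),
                "NS": float(sv.NS),
                "degeneracy_class": gc.degeneracy_class(codon),
                "is_pretermination": gc.is_pretermination(codon),
            }
        )
    if include_stops:
        for codon in sorted(gc.STOP_CODONS):
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": "*",
                    "S": float("nan"),
                    "NS": float("nan"),
                    "degeneracy_class": "stop",
                    "is_pretermination": False,
                }
            )
    return pd.DataFrame(rows).sort_values("codon", kind="stable").reset_index(drop=True)


def table_totals(table: pd.DataFrame) -> tuple[float, float]:
    """(total_S, total_NS) over the sense-codon rows, summed unrounded
    and reported to 3 decimals."""
    sense = table.dropna(subset=["S", "NS"])
    return round3(float(sense["S"].sum())), round3(float(sense["NS"].sum()))
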