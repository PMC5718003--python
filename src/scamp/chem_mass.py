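"""Molecular-formula arithmetic for negative-mode metabolite annotation.

Monoisotopic masses of the light isotopes (1H, 12C, 14N, 16O, 32S, 31P)
follow the NIST recommended values.  Deprotonation uses the proton mass
(M - m(H) + m(e-)), so the electron mass is retained: dropping it shifts
every [M-H]- value by ~0.55 mDa, which is an order of magnitude above the
accuracy of a 15 T FT-ICR instrument.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ChemicalFormula",
    "MONOISOTOPIC_MASS",
    "C13_DELTA",
    "PROTON_MASS",
    "parse_formula",
    "render_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "carbon13_shift",
    "match_formula",
    "read_candidate_formulas",
]

#: Monoisotopic atomic masses in Da (NIST).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: mass(13C) - mass(12C) in Da; the spacing of carbon isotopologue satellites.
C13_DELTA = 1.0033548378

#: Proton mass in Da, i.e. m(1H) - m(e-).
PROTON_MASS = 1.00727646688

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition over the supported element set.

    ``element_counts`` maps element symbol to a positive integer count.
    Instances are immutable and hashable so they can key dictionaries of
    candidate compounds.
    """

    element_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise ValueError("empty formula")
        for symbol, count in self.element_counts:
            if symbol not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element symbol: {symbol!r}")
            if not isinstance(count, int) or count <= 0:
                raise ValueError(f"count for {symbol} must be a positive integer")

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def count(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_formula(self)


def _hill_order(counts: dict[str, int]) -> tuple[tuple[str, int], ...]:
    # Hill convention: C, then H, then the rest alphabetically.
    order = [s for s in ("C", "H") if s in counts]
    order += sorted(s for s in counts if s not in ("C", "H"))
    return tuple((s, counts[s]) for s in order)


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string such as ``"C7H6O5"``.

    An omitted count means 1.  Raises ``ValueError`` naming the offending
    token on unsupported elements or malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"malformed formula near {text[pos:match.start()]!r}")
        symbol, digits = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element symbol: {symbol!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula near {text[pos:]!r}")
    return ChemicalFormula(_hill_order(counts))


def render_formula(f: ChemicalFormula) -> str:
    """Render a formula back to its Hill-notation string."""
    return "".join(
        symbol if count == 1 else f"{symbol}{count}"
        for symbol, count in _hill_order(f.counts)
    )


def monoisotopic_mass(f: ChemicalFormula) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic mass."""
    return sum(MONOISOTOPIC_MASS[s] * n for s, n in f.element_counts)


def deprotonated_mz(f: ChemicalFormula) -> float:
    """m/z of the [M-H]- ion: neutral mass minus the proton mass.

    Requires at least one hydrogen to remove.
    """
    if f.count("H") < 1:
        raise ValueError("formula has no hydrogen to deprotonate")
    return monoisotopic_mass(f) - PROTON_MASS


def carbon13_shift(n: int) -> float:
    """Mass shift in Da of the +n carbon-13 isotopologue, n in 1..3."""
    if not isinstance(n, int) or not 1 <= n <= 3:
        raise ValueError("isotopologue order must be an integer in 1..3")
    return n * C13_DELTA


def match_formula(
    observed_mz: float,
    candidates: list[ChemicalFormula],
    tol: float,
) -> list[tuple[ChemicalFormula, float, bool]]:
    """Match an observed [M-H]- m/z against candidate formulas.

    Returns ``(formula, signed error in mDa, within_tol)`` triples sorted
    by absolute error ascending.  ``error = (observed - calculated) * 1000``.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    out = []
    for f in candidates:
        err = (observed_mz - deprotonated_mz(f)) * 1000.0
        out.append((f, err, abs(err) <= tol))
    out.sort(key=lambda t: abs(t[1]))
    return out


def read_candidate_formulas(path) -> list[tuple[str, ChemicalFormula]]:
    """Read a two-column TSV (name, Hill formula) of candidate compounds."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("candidate table needs two columns: name, formula")
    name_col, formula_col = table.columns[:2]
    return [
        (str(row[name_col]), parse_formula(str(row[formula_col])))
        for _, row in table.iterrows()
    ]
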