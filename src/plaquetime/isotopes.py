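"""Peptide elemental compositions and isotopologue patterns under partial 15N enrichment.

Metabolic labeling with a 15N diet shifts and broadens the isotopologue
envelope of a peptide: every nitrogen atom carries the label with some
probability ``q`` (the body-pool enrichment), while C/H/O/S isotopes stay
at natural abundance.  This module computes the resulting theoretical
isotopologue pattern exactly, by convolving per-element isotope
distributions and aggregating into nominal-mass bins.  It is the oracle
for the reflector-mode nitrogen index (the 4th/3rd isotopologue peak-area
ratio) and for the spectrum simulator.

Nominal-mass binning merges the 13C and 15N fine structure (0.0063 Da
apart), which is unresolvable at m/dm = 15000; each bin's centroid is the
abundance-weighted mean exact mass of its fine isotopologues.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeptideComposition",
    "EnrichmentParams",
    "IsotopologuePattern",
    "ABETA42_SEQUENCE",
    "composition_from_sequence",
    "monoisotopic_mass",
    "monoisotopic_mz",
    "isotopologue_pattern",
    "pattern_centroid",
    "theoretical_peak_ratio",
    "enumerate_pattern_bruteforce",
    "PROTON_MASS",
]

PROTON_MASS = 1.007276

#: Monoisotopic (lightest-isotope) atomic masses, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
}

#: Exact masses of the heavier isotopes used in the fine pattern, Da.
ISOTOPE_MASS = {
    "C": {0: 12.0, 1: 13.00335484},
    "H": {0: 1.00782503, 1: 2.01410178},
    "N": {0: 14.0030740, 1: 15.0001089},
    "O": {0: 15.9949146, 1: 16.9991315, 2: 17.9991596},
    "S": {0: 31.9720707, 1: 32.9714589, 2: 33.9678668, 4: 35.9670808},
}

#: Natural isotope abundances keyed by element and nominal-mass offset.
NATURAL_ABUNDANCE = {
    "C": {0: 1.0 - 0.0107, 1: 0.0107},
    "H": {0: 1.0 - 0.000115, 1: 0.000115},
    "N": {0: 1.0 - 0.00364, 1: 0.00364},
    "O": {0: 1.0 - 0.00038 - 0.00205, 1: 0.00038, 2: 0.00205},
    "S": {0: 1.0 - 0.0075 - 0.0429 - 0.0001, 1: 0.0075, 2: 0.0429, 4: 0.0001},
}

N15_NATURAL = 0.00364
#: Mass difference 15N - 14N, Da.
DELTA_M_15N = ISOTOPE_MASS["N"][1] - ISOTOPE_MASS["N"][0]

# Residue formulas (monomer minus water), one-letter codes.
_RESIDUE_FORMULA = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Human amyloid-beta 1-42, the species measured throughout.
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"


@dataclass(frozen=True)
class PeptideComposition:
    """Elemental composition of a peptide (C, H, N, O, S counts)."""

    element_counts: dict

    def __post_init__(self):
        for el, n in self.element_counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    @property
    def nitrogen_count(self) -> int:
        return self["N"]

    def to_json(self) -> str:
        return json.dumps(self.element_counts, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PeptideComposition":
        return cls(json.loads(s))


@dataclass(frozen=True)
class EnrichmentParams:
    """15N labeling state: ``q`` is the probability any one nitrogen is 15N."""

    q: float = N15_NATURAL
    natural_abundances: dict = field(default_factory=lambda: NATURAL_ABUNDANCE)

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        for el, ab in self.natural_abundances.items():
            if abs(sum(ab.values()) - 1.0) > 1e-9:
                raise ValueError(f"abundances for {el} do not sum to 1")

    def element_distribution(self, element: str) -> dict:
        """Single-atom isotope distribution {nominal offset: probability}."""
        if element == "N":
            return {0: 1.0 - self.q, 1: self.q}
        return dict(self.natural_abundances[element])


@dataclass(frozen=True)
class IsotopologuePattern:
    """Discrete (mass, abundance) distribution over nominal-mass bins.

    Bin ``k`` aggregates all fine isotopologues with nominal mass
    ``nominal(mono) + k``; ``masses[k]`` is the abundance-weighted mean
    exact mass within the bin.
    """

    masses: np.ndarray
    abundances: np.ndarray
    enrichment_q: float

    def __post_init__(self):
        m = np.asarray(self.masses, float)
        a = np.asarray(self.abundances, float)
        if m.size != a.size or m.size == 0:
            raise ValueError("masses and abundances must be non-empty, same length")
        if np.any(np.diff(m) <= 0):
            raise ValueError("masses must be strictly increasing")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "abundances", a)

    def __len__(self) -> int:
        return len(self.masses)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.masses, self.abundances]),
                   delimiter=",", header="mass,abundance", comments="")


def composition_from_sequence(sequence: str, termini: str = "free") -> PeptideComposition:
    """Sum residue formulas; free termini add one water.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid codes (20 canonical residues).
    termini : {"free", "none"}
        "free" adds H2O for the uncondensed N/C termini; "none" returns the
        bare residue-sum (useful for internal fragments).
    """
    counts: dict = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
    for i, aa in enumerate(sequence):
        f = _RESIDUE_FORMULA.get(aa)
        if f is None:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        for el, n in f.items():
            counts[el] += n
    if termini == "free":
        counts["H"] += 2
        counts["O"] += 1
    elif termini != "none":
        raise ValueError(f"unknown termini mode {termini!r}")
    return PeptideComposition({el: n for el, n in counts.items() if n > 0})


def monoisotopic_mass(comp: PeptideComposition) -> float:
    """Neutral monoisotopic (all-lightest-isotope) mass in Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in comp.element_counts.items())


def monoisotopic_mz(comp: PeptideComposition, charge: int = 1) -> float:
    """m/z of the [M + charge*H]^charge+ monoisotopic ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(comp) + charge * PROTON_MASS) / charge


def _convolve_tracked(p1, m1, p2, m2):
    """Convolve two (probability, probability*mass-shift) array pairs."""
    p = np.convolve(p1, p2)
    m = np.convolve(p1, m2) + np.convolve(m1, p2)
    return p, m


def _element_pattern(element: str, n_atoms: int, dist: dict):
    """Pattern of n identical atoms: arrays over nominal-mass offset."""
    kmax = max(dist)
    p1 = np.zeros(kmax + 1)
    m1 = np.zeros(kmax + 1)
    mono = ISOTOPE_MASS[element][0]
    for k, prob in dist.items():
        p1[k] = prob
        m1[k] = prob * (ISOTOPE_MASS[element][k] - mono)
    # binary exponentiation of the single-atom polynomial
    p, m = np.array([1.0]), np.array([0.0])
    base_p, base_m = p1, m1
    n = n_atoms
    while n:
        if n & 1:
            p, m = _convolve_tracked(p, m, base_p, base_m)
        n >>= 1
        if n:
            base_p, base_m = _convolve_tracked(base_p, base_m, base_p, base_m)
    return p, m


def isotopologue_pattern(
    comp: PeptideComposition,
    params: EnrichmentParams | float | None = None,
    prune: float = 1e-10,
    charge: int = 0,
) -> IsotopologuePattern:
    """Theoretical isotopologue pattern of ``comp`` at enrichment ``params.q``.

    Exact within nominal-mass aggregation: per-element multinomial isotope
    distributions are convolved over all atoms, tracking per-bin probability
    and mean exact mass.  Bins below ``prune`` (relative abundance) are
    dropped and the remainder renormalized.

    ``charge > 0`` shifts masses to the [M+zH]z+ m/z scale.
    """
    if params is None:
        params = EnrichmentParams()
    elif isinstance(params, (int, float)):
        params = EnrichmentParams(q=float(params))
    if not 0.0 <= prune <= 1e-4:
        raise ValueError("prune must be in [0, 1e-4]")

    p = np.array([1.0])
    m = np.array([0.0])
    for el, n in comp.element_counts.items():
        if n == 0:
            continue
        pe, me = _element_pattern(el, n, params.element_distribution(el))
        p, m = _convolve_tracked(p, m, pe, me)

    mono = monoisotopic_mass(comp)
    keep = p > prune
    p_kept = p[keep]
    # bin centroid = mono + (sum prob*shift)/(sum prob) within the bin
    masses = mono + m[keep] / p_kept
    abundances = p_kept / p_kept.sum()
    if charge:
        masses = (masses + charge * PROTON_MASS) / charge
    return IsotopologuePattern(masses=masses, abundances=abundances,
                               enrichment_q=params.q)


def pattern_centroid(pattern: IsotopologuePattern) -> float:
    """Abundance-weighted mean mass of the pattern, Da."""
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    return float(np.average(pattern.masses, weights=pattern.abundances))


def theoretical_peak_ratio(pattern: IsotopologuePattern, i: int, j: int) -> float:
    """Abundance ratio of the i-th to j-th isotopologue bins (1-based from
    the monoisotopic bin).  i=4, j=3 is the reflector-mode nitrogen index."""
    for idx in (i, j):
        if idx < 1 or idx > len(pattern):
            raise ValueError(f"isotopologue bin {idx} not present in pattern")
        if pattern.abundances[idx - 1] <= 0:
            raise ValueError(f"isotopologue bin {idx} has zero abundance")
    return float(pattern.abundances[i - 1] / pattern.abundances[j - 1])


def enumerate_pattern_bruteforce(comp: PeptideComposition,
                                 params: EnrichmentParams) -> IsotopologuePattern:
    """Exhaustive multinomial enumeration over per-atom isotope assignments.

    Exponential in atom count — an independent oracle for tiny compositions
    (<= ~6 atoms), not for real peptides.
    """
    atoms = []
    for el, n in comp.element_counts.items():
        atoms.extend([el] * n)
    dist = {el: params.element_distribution(el) for el in set(atoms)}
    bins: dict = {}
    choices = [list(dist[el].items()) for el in atoms]
    for assignment in itertools.product(*choices):
        prob = 1.0
        shift_nominal = 0
        shift_mass = 0.0
        for el, (k, pk) in zip(atoms, assignment):
            prob *= pk
            shift_nominal += k
            shift_mass += ISOTOPE_MASS[el][k] - ISOTOPE_MASS[el][0]
        acc = bins.setdefault(shift_nominal, [0.0, 0.0])
        acc[0] += prob
        acc[1] += prob * shift_mass
    mono = monoisotopic_mass(comp)
    ks = sorted(k for k in bins if bins[k][0] > 0)
    p = np.array([bins[k][0] for k in ks])
    masses = mono + np.array([bins[k][1] for k in ks]) / p
    return IsotopologuePattern(masses=masses, abundances=p / p.sum(),
                               enrichment_q=params.q)
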