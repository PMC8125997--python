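"""Excitation/sensing electrode configuration algebra.

A single tomographic measurement uses a quadruple q = (a, b, m, n) of
distinct electrodes on a ring of L: current is driven between a and b,
potential sensed between m and n.  The full configuration space is

    Q(L) = { (a,b,m,n) : pairwise distinct, each in [1, L] },
    |Q(L)| = L! / (L-4)! = L (L-1) (L-2) (L-3),

while a hardware design with *dedicated* electrodes fixes each electrode's
role once and for all around the ring in the repeating pattern a, b, m, n:
a-electrodes at positions 1, 5, 9, ..., b at 2, 6, 10, ..., m at 3, 7, 11,
..., n at 4, 8, 12, ....  The dedicated set Qd(L) is the Cartesian product
of the four role classes, |Qd(L)| = (L/4)^4, so |Qd|/|Q| -> 4^-4 (~0.39%)
as L grows.  Electrode indexing is 1-based throughout, with electrode e1
at angle 0 and the ring counter-clockwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations, product

import numpy as np

__all__ = [
    "Quadruple",
    "ConfigSet",
    "ElectrodeRing",
    "enumerate_full",
    "enumerate_dedicated",
    "dedicated_role_positions",
    "adjacent_opposite_count",
    "scheme_ratios",
    "ring_distance",
    "classify_by_excitation_distance",
]


@dataclass(frozen=True)
class Quadruple:
    """One measurement configuration (a, b, m, n), 1-based electrode ids."""

    a: int
    b: int
    m: int
    n: int

    def validate(self, L: int) -> None:
        ids = (self.a, self.b, self.m, self.n)
        if len(set(ids)) != 4:
            raise ValueError(f"quadruple {ids} has repeated electrodes")
        if any(not (1 <= e <= L) for e in ids):
            raise ValueError(f"quadruple {ids} out of range [1, {L}]")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.m, self.n)


@dataclass(frozen=True)
class ElectrodeRing:
    """L equispaced electrodes on a circle, e1 at angle 0, counter-clockwise."""

    L: int
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.L < 4:
            raise ValueError("need at least 4 electrodes")
        if not (self.radius > 0):
            raise ValueError("radius must be > 0")

    @property
    def angles(self) -> np.ndarray:
        """Angle of each electrode (radians), index 0 holds e1."""
        return 2.0 * np.pi * np.arange(self.L) / self.L

    def angle_of(self, electrode: int) -> float:
        """Angle of a 1-based electrode index."""
        if not (1 <= electrode <= self.L):
            raise ValueError(f"electrode {electrode} out of range [1, {self.L}]")
        return 2.0 * np.pi * (electrode - 1) / self.L

    def positions(self) -> np.ndarray:
        th = self.angles
        return self.radius * np.column_stack([np.cos(th), np.sin(th)])


@dataclass(frozen=True)
class ConfigSet:
    """An ordered list of quadruples over a ring of L electrodes."""

    L: int
    quadruples: tuple[Quadruple, ...]
    scheme: str = "custom"

    def __post_init__(self) -> None:
        for q in self.quadruples:
            q.validate(self.L)

    def __len__(self) -> int:
        return len(self.quadruples)

    def __iter__(self):
        return iter(self.quadruples)

    def __getitem__(self, i):
        return self.quadruples[i]

    def as_array(self) -> np.ndarray:
        """N x 4 integer array of (a, b, m, n) rows in set order."""
        return np.array([q.as_tuple() for q in self.quadruples], dtype=np.int64)

    def excitation_pairs(self) -> list[tuple[int, int]]:
        """Distinct (a, b) pairs in first-appearance order."""
        seen: dict[tuple[int, int], None] = {}
        for q in self.quadruples:
            seen.setdefault((q.a, q.b), None)
        return list(seen)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "a", "b", "m", "n", "d_ab"])
            for i, q in enumerate(self.quadruples):
                w.writerow([i, q.a, q.b, q.m, q.n, ring_distance(q.a, q.b, self.L)])

    @classmethod
    def from_csv(cls, path, scheme: str = "custom") -> "ConfigSet":
        quads = []
        L = 0
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                q = Quadruple(int(row["a"]), int(row["b"]), int(row["m"]), int(row["n"]))
                L = max(L, *q.as_tuple())
                quads.append(q)
        return cls(L=L, quadruples=tuple(quads), scheme=scheme)


def enumerate_full(L: int) -> ConfigSet:
    """All ordered quadruples of distinct electrodes, lexicographic order.

    |Q(L)| = L (L-1) (L-2) (L-3); for L = 16 that is 43,680.
    """
    if L < 4:
        raise ValueError("L must be >= 4")
    quads = tuple(Quadruple(*p) for p in permutations(range(1, L + 1), 4))
    return ConfigSet(L=L, quadruples=quads, scheme="full")


def dedicated_role_positions(L: int) -> dict[str, list[int]]:
    """1-based electrode positions of each dedicated role class.

    Role j of quadruple k sits at electrode 4(k-1) + j, i.e. a-electrodes
    at 1, 5, 9, ..., b at 2, 6, 10, ..., m at 3, 7, 11, ..., n at 4, 8,
    12, ....  Requires L divisible by 4 (the repeating 4-role pattern must
    close around the ring; the design's stated L = 2M, M >= 2 is the
    looser necessary condition).
    """
    if L < 8 or L % 4 != 0:
        raise ValueError("dedicated scheme requires L >= 8 and L divisible by 4")
    return {
        "a": [4 * k + 1 for k in range(L // 4)],
        "b": [4 * k + 2 for k in range(L // 4)],
        "m": [4 * k + 3 for k in range(L // 4)],
        "n": [4 * k + 4 for k in range(L // 4)],
    }


def enumerate_dedicated(L: int) -> ConfigSet:
    """Dedicated configuration set Qd(L): Cartesian product of role classes.

    Row-major over (a-class, b-class, m-class, n-class); |Qd(L)| = (L/4)^4.
    """
    roles = dedicated_role_positions(L)
    quads = tuple(
        Quadruple(a, b, m, n)
        for a, b, m, n in product(roles["a"], roles["b"], roles["m"], roles["n"])
    )
    return ConfigSet(L=L, quadruples=quads, scheme="dedicated")


def adjacent_opposite_count(L: int) -> int:
    """Configuration count L(L-3) of the full-circle adjacent/opposite
    scan strategies (both directions, all excitation placements)."""
    if L < 4:
        raise ValueError("L must be >= 4")
    return L * (L - 3)


def scheme_ratios(L: int) -> dict:
    """Exact size ratios of the measurement schemes at a given L.

    Returns |Q|, |Qd|, their exact ratio (Fraction) and float value, the
    asymptotic dedicated ratio 4^-4, and the adjacent/opposite count
    L(L-3) with its ratio 1/(L^2 - 3L + 3) relative to |Q(L)|.
    """
    if L < 8 or L % 4 != 0:
        raise ValueError("dedicated scheme requires L >= 8 and L divisible by 4")
    n_full = L * (L - 1) * (L - 2) * (L - 3)
    n_ded = (L // 4) ** 4
    ratio = Fraction(n_ded, n_full)
    adj = adjacent_opposite_count(L)
    return {
        "L": L,
        "n_full": n_full,
        "n_dedicated": n_ded,
        "dedicated_ratio": ratio,
        "dedicated_ratio_float": float(ratio),
        "dedicated_ratio_limit": Fraction(1, 4**4),
        "adjacent_opposite_count": adj,
        "adjacent_opposite_ratio": Fraction(1, L * L - 3 * L + 3),
    }


def ring_distance(i: int, j: int, L: int) -> int:
    """Circular index distance d(i, j) = min(|i-j|, L - |i-j|), i != j."""
    if not (1 <= i <= L and 1 <= j <= L):
        raise ValueError(f"electrode indices must lie in [1, {L}]")
    if i == j:
        raise ValueError("ring distance requires distinct electrodes")
    d = abs(i - j)
    return min(d, L - d)


def classify_by_excitation_distance(cfg: ConfigSet) -> dict[int, list[int]]:
    """Partition quadruple indices by the excitation ring distance d(a, b).

    For Qd(16) this yields exactly the classes d in {1, 3, 5, 7}, each
    holding 4 excitation pairs x 16 sensing combinations = 64 quadruples.
    """
    out: dict[int, list[int]] = {}
    for idx, q in enumerate(cfg.quadruples):
        d = ring_distance(q.a, q.b, cfg.L)
        out.setdefault(d, []).append(idx)
    return dict(sorted(out.items()))
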