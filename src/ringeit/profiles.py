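"""Sorted potential-profile analysis.

Instead of displaying the N measured responses in their arbitrary
acquisition order, the responses are sorted ascending,
y_(1) <= y_(2) <= ... <= y_(N), defining a *potential profile* together
with the permutation mapping ranks back to configurations.  On an axially
symmetric (homogeneous) tank with equispaced electrodes the profile of an
excitation pair depends only on the ring distance d(a, b) of that pair,
so the 256 dedicated-scheme measurements of a 16-electrode ring collapse
to four distinct 16-value profiles (d = 1, 3, 5, 7) - 64 informative
responses.  An inclusion breaks the symmetry and permutes the reference
ordering locally, which `compare_profiles` quantifies (per-rank index
displacement and Kendall-tau permutation distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .configs import ConfigSet, ring_distance

__all__ = [
    "MeasurementSet",
    "PotentialProfile",
    "ProfileStructure",
    "sort_profile",
    "compare_profiles",
    "mean_response",
    "profile_structure",
    "UNIQUENESS_RTOL",
]

#: two noiseless responses are treated as equal when their relative
#: difference is below this tolerance
UNIQUENESS_RTOL = 1e-6


@dataclass
class MeasurementSet:
    """Response matrix Y (N configs x W samples) with its configuration."""

    Y: np.ndarray
    configs: ConfigSet
    sample_times: np.ndarray
    waveform: dict | None = None

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[0] != len(self.configs):
            raise ValueError("Y row count must equal the configuration count")
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.sample_times.size != self.Y.shape[1]:
            raise ValueError("sample_times length must equal the column count of Y")

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def W(self) -> int:
        return self.Y.shape[1]

    def to_csv(self, path) -> None:
        cfg = self.configs.as_array()
        d = np.array([ring_distance(a, b, self.configs.L) for a, b, _, _ in cfg])
        arr = np.column_stack([cfg, d, self.Y])
        header = "a,b,m,n,d_ab," + ",".join(f"y{w}" for w in range(self.W))
        np.savetxt(path, arr, delimiter=",", header=header, comments="")


@dataclass
class PotentialProfile:
    """Ascending-sorted responses with their configuration permutation."""

    sorted_values: np.ndarray
    permutation: np.ndarray  # original row index at each sorted rank
    distance_class: int | None = None  # excitation ring distance, if uniform

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sorted_values) < 0):
            raise ValueError("sorted_values must be non-decreasing")
        if sorted(self.permutation.tolist()) != list(range(self.permutation.size)):
            raise ValueError("permutation must be a bijection on row indices")

    @property
    def N(self) -> int:
        return self.sorted_values.size

    def to_csv(self, path) -> None:
        arr = np.column_stack([np.arange(self.N), self.permutation, self.sorted_values])
        np.savetxt(path, arr, delimiter=",", header="rank,config_index,value", comments="")


def _reduce(ms: MeasurementSet, column_reducer: str, column: int) -> np.ndarray:
    if ms.Y.size == 0:
        raise ValueError("empty measurement set")
    if column_reducer == "window_mean":
        return ms.Y.mean(axis=1)
    if column_reducer == "single_column":
        return ms.Y[:, column]
    raise ValueError("column_reducer must be 'window_mean' or 'single_column'")


def sort_profile(
    ms: MeasurementSet,
    column_reducer: str = "window_mean",
    column: int = 0,
) -> tuple[PotentialProfile, dict[tuple[int, int], PotentialProfile]]:
    """Global sorted profile plus one profile per excitation pair.

    Sorting is stable (ties keep acquisition order) so the permutation is
    reproducible.  Per-pair profiles are keyed by (a, b) and carry the
    excitation ring distance of that pair as their distance class.
    """
    vals = _reduce(ms, column_reducer, column)
    perm = np.argsort(vals, kind="stable")
    global_profile = PotentialProfile(sorted_values=vals[perm], permutation=perm)

    per_pair: dict[tuple[int, int], PotentialProfile] = {}
    pair_rows: dict[tuple[int, int], list[int]] = {}
    for idx, q in enumerate(ms.configs):
        pair_rows.setdefault((q.a, q.b), []).append(idx)
    for pair, rows in pair_rows.items():
        rows = np.array(rows)
        v = vals[rows]
        p = np.argsort(v, kind="stable")
        per_pair[pair] = PotentialProfile(
            sorted_values=v[p],
            permutation=p,
            distance_class=ring_distance(pair[0], pair[1], ms.configs.L),
        )
    return global_profile, per_pair


def compare_profiles(ref: PotentialProfile, test: PotentialProfile) -> dict:
    """Permutation-change report between two profiles of the same set.

    Reports the per-rank index displacement (which configuration occupies
    each rank, reference vs test), the number of displaced ranks, and the
    Kendall-tau distance (number of pairwise order inversions; the
    bubble-sort distance between the two orderings, 0 for identical
    orderings and N(N-1)/2 for a full reversal).
    """
    if ref.N != test.N:
        raise ValueError("profiles must have the same length")
    n = ref.N
    # rank of each configuration in either ordering
    rank_ref = np.empty(n, dtype=np.int64)
    rank_ref[ref.permutation] = np.arange(n)
    rank_test = np.empty(n, dtype=np.int64)
    rank_test[test.permutation] = np.arange(n)
    displacement = rank_test - rank_ref
    # inversions of the test ranking traversed in reference order
    seq = rank_test[ref.permutation]
    inversions = int(np.triu(seq[:, None] > seq[None, :], k=1).sum())
    displaced = int(np.count_nonzero(displacement))
    return {
        "displacement": displacement,
        "displaced_ranks": displaced,
        "kendall_tau_distance": inversions,
        "max_kendall_tau_distance": n * (n - 1) // 2,
    }


def mean_response(ms: MeasurementSet, scale: bool = False) -> np.ndarray:
    """Row-wise mean response <y> over the sample window, per config.

    With ``scale`` the means are affinely mapped to [0, 1] across
    configurations; a constant vector makes that map degenerate and
    returns zeros with a warning.
    """
    m = ms.Y.mean(axis=1)
    if not scale:
        return m
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 1e-300 or (hi - lo) < 1e-12 * max(abs(hi), abs(lo)):
        import warnings

        warnings.warn("constant mean responses; scaled output set to zeros", stacklevel=2)
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


@dataclass
class ProfileStructure:
    """Degeneracy structure of a measurement vector under symmetry.

    ``n_unique_responses`` counts responses the way the symmetry argument
    does: (number of distinct per-excitation-pair profiles) x (responses
    per profile).  ``n_unique_values`` is the raw count of numerically
    distinct scalars, which on an ideally symmetric tank is *smaller*
    because reciprocity and reflection produce additional exact value
    coincidences across configurations (see the methods notes).
    """

    n_profile_classes: int
    profile_length: int
    n_unique_responses: int
    n_unique_values: int
    class_of_pair: dict[tuple[int, int], int]
    distance_of_pair: dict[tuple[int, int], int]


def _count_groups(sorted_vals: np.ndarray, rtol: float) -> int:
    if sorted_vals.size == 0:
        return 0
    scale = max(float(np.max(np.abs(sorted_vals))), 1e-300)
    groups = 1
    for k in range(1, sorted_vals.size):
        if abs(sorted_vals[k] - sorted_vals[k - 1]) > rtol * scale:
            groups += 1
    return groups


def profile_structure(
    values: np.ndarray,
    cfg: ConfigSet,
    rtol: float = UNIQUENESS_RTOL,
) -> ProfileStructure:
    """Group per-excitation-pair profiles and count unique responses.

    Two excitation pairs belong to the same profile class when their
    sorted response vectors agree to relative tolerance ``rtol``
    (referenced to the largest response magnitude).
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(cfg):
        raise ValueError("values length must equal the configuration count")
    pair_rows: dict[tuple[int, int], list[int]] = {}
    for idx, q in enumerate(cfg):
        pair_rows.setdefault((q.a, q.b), []).append(idx)
    profiles = {pair: np.sort(values[rows]) for pair, rows in pair_rows.items()}
    lengths = {v.size for v in profiles.values()}
    if len(lengths) != 1:
        raise ValueError("excitation pairs have unequal sensing counts")
    (plen,) = lengths
    scale = max(float(np.max(np.abs(values))), 1e-300)

    class_reps: list[np.ndarray] = []
    class_of_pair: dict[tuple[int, int], int] = {}
    for pair, prof in profiles.items():
        for ci, rep in enumerate(class_reps):
            if np.max(np.abs(prof - rep)) <= rtol * scale:
                class_of_pair[pair] = ci
                break
        else:
            class_of_pair[pair] = len(class_reps)
            class_reps.append(prof)

    return ProfileStructure(
        n_profile_classes=len(class_reps),
        profile_length=plen,
        n_unique_responses=len(class_reps) * plen,
        n_unique_values=_count_groups(np.sort(values), rtol),
        class_of_pair=class_of_pair,
        distance_of_pair={
            pair: ring_distance(pair[0], pair[1], cfg.L) for pair in profiles
        },
    )
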