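"""Community comparison and the producer/consumer-versus-climate tests.

Bray-Curtis dissimilarities between fingerprint profiles feed three
downstream analyses: group-average hierarchical clustering cut at a fixed
dissimilarity (40% by default), non-metric multidimensional scaling (NMDS,
Kruskal stress-1 with monotone regression), and ordinary least-squares
regression of the producer/consumer ratio on macroclimate predictors with an
order-of-magnitude outlier screen.

Profiles from different samples are aligned onto a common set of fragment
bins by re-running the 1 bp single-linkage chaining over all samples'
representative sizes before any pairwise comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression

from .errors import ValidationError
from .io import SiteMetadata
from .trflp import CommunityProfile, chain_bins

PREDICTORS = ("growing_season_d", "map_mm", "tmin_c", "tmax_c")


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 sum(min) / (sum a + sum b)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("abundance vectors differ in length")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValidationError("both abundance vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def align_profiles(
    profiles: Sequence[CommunityProfile], tol_bp: float = 1.0
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Place all samples on one common bin set.

    Representative sizes from every sample are chained with the same 1 bp
    single-linkage rule used within samples; each chain becomes a column.
    Returns (sample_ids, column representative sizes, abundance matrix).
    """
    sample_ids = [p.sample_id for p in profiles]
    flat: list[tuple[int, float, float]] = []
    for si, p in enumerate(profiles):
        for rep, ab in p.abundances.items():
            flat.append((si, rep, ab))
    sizes = [rep for _, rep, _ in flat]
    groups = chain_bins(sizes, tol_bp)
    reps = np.array([float(np.mean([sizes[i] for i in g])) for g in groups])
    matrix = np.zeros((len(profiles), len(groups)))
    for col, g in enumerate(groups):
        for i in g:
            si, _, ab = flat[i]
            matrix[si, col] += ab
    return sample_ids, reps, matrix


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def dissimilarity_matrix(
    profiles: Sequence[CommunityProfile], tol_bp: float = 1.0
) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis over aligned profiles."""
    if len(profiles) < 2:
        raise ValidationError("need at least two samples")
    ids, _, matrix = align_profiles(profiles, tol_bp)
    d = squareform(pdist(matrix, metric="braycurtis"))
    return DissimilarityMatrix(ids=ids, matrix=d)


def cluster_groups(dm: DissimilarityMatrix, cutoff: float = 0.40) -> dict[str, int]:
    """Group-average (UPGMA) clustering cut at ``cutoff`` dissimilarity.

    Labels are 1..k in order of each group's first member in the input.
    """
    z = linkage(dm.condensed(), method="average")
    raw = fcluster(z, t=cutoff, criterion="distance")
    relabel: dict[int, int] = {}
    out = {}
    for sid, lab in zip(dm.ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[sid] = relabel[lab]
    return out


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class NMDSResult:
    coordinates: np.ndarray  # n x k
    stress: float            # Kruskal stress-1 of the best start
    stress_history: list[float]  # accepted-iteration stresses, non-increasing
    n_starts: int
    seed: int | None
    converged: bool
    ids: list[str] | None = None


def kruskal_stress(dvec: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against condensed dissimilarities,
    with disparities fitted by monotone (isotonic) regression."""
    d = pdist(coords)
    denom = float((d ** 2).sum())
    if denom == 0:
        return math.inf
    dhat = IsotonicRegression(increasing=True).fit_transform(dvec, d)
    return float(math.sqrt(((d - dhat) ** 2).sum() / denom))


def _fit_disparities(dvec: np.ndarray, coords: np.ndarray):
    d = pdist(coords)
    denom = float((d ** 2).sum())
    if denom == 0:
        return math.inf, d, d
    dhat = IsotonicRegression(increasing=True).fit_transform(dvec, d)
    stress = float(math.sqrt(((d - dhat) ** 2).sum() / denom))
    return stress, dhat, d


def _guttman_step(coords: np.ndarray, dhat: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    b = -squareform(ratio)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ coords / n


def classical_mds(d_matrix: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling, used as the deterministic first start."""
    n = d_matrix.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d_matrix ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def _nmds_single(dvec, x0, max_iter, tol):
    x = x0.copy()
    stress, dhat, d = _fit_disparities(dvec, x)
    history = [stress]
    converged = False
    for _ in range(max_iter):
        cand = _guttman_step(x, dhat, d)
        s_c, dh_c, d_c = _fit_disparities(dvec, cand)
        accepted = False
        for _ in range(6):  # step-halving toward the current configuration
            if s_c < stress - 1e-15:
                accepted = True
                break
            cand = 0.5 * (cand + x)
            s_c, dh_c, d_c = _fit_disparities(dvec, cand)
        if not accepted:
            converged = True
            break
        improvement = stress - s_c
        x, stress, dhat, d = cand, s_c, dh_c, d_c
        history.append(stress)
        if improvement < tol:
            converged = True
            break
    return x, stress, history, converged


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Center and rotate to principal axes with a fixed sign convention, so
    results are reproducible up to the rotation/reflection the stress ignores."""
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        i = np.argmax(np.abs(x[:, j]))
        if x[i, j] < 0:
            x[:, j] = -x[:, j]
    return x


def nmds(
    dm: DissimilarityMatrix | np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Disparities are fitted by pool-adjacent-violators monotone regression of
    configuration distances on the observed dissimilarities; coordinates are
    updated by Guttman transforms with step-halving so that the stress of
    accepted iterations never increases.  The first start is the classical
    metric-MDS configuration, the rest are random; the best final stress is
    reported.
    """
    if isinstance(dm, DissimilarityMatrix):
        ids, d_matrix = dm.ids, dm.matrix
    else:
        ids, d_matrix = None, np.asarray(dm, dtype=float)
    n = d_matrix.shape[0]
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} samples for {k}-D NMDS")
    dvec = squareform(d_matrix, checks=False)
    degenerate = bool(np.ptp(dvec) == 0)
    if degenerate:
        warnings.warn("all dissimilarities equal; NMDS configuration is degenerate")

    rng = np.random.default_rng(seed)
    starts = [classical_mds(d_matrix, k)]
    scale = max(dvec.max(), 1e-12)
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(scale=scale, size=(n, k)))

    best = None
    for x0 in starts:
        x, stress, history, converged = _nmds_single(dvec, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, history, converged)
    x, stress, history, converged = best
    return NMDSResult(
        coordinates=_canonical_orientation(x),
        stress=stress,
        stress_history=history,
        n_starts=len(starts),
        seed=seed,
        converged=converged and not degenerate,
        ids=ids,
    )


# ---------------------------------------------------------------------------
# P/C versus climate

def remove_pc_outliers(
    pc_values: Mapping[str, float], site_labels: Mapping[str, str]
) -> tuple[dict[str, float], list[str]]:
    """Drop communities whose P/C exceeds both its location mean and the
    overall mean by an order of magnitude (>= 10x), means computed without
    the candidate.  A location's sole member has no peer mean and is kept.
    """
    ids = list(pc_values)
    if len(ids) < 2:
        raise ValidationError("need at least two samples for outlier screening")
    excluded = []
    for sid in ids:
        v = pc_values[sid]
        if not math.isfinite(v):
            excluded.append(sid)
            continue
        loc = site_labels.get(sid, "")
        peers_loc = [pc_values[o] for o in ids
                     if o != sid and site_labels.get(o, "") == loc
                     and math.isfinite(pc_values[o])]
        peers_all = [pc_values[o] for o in ids
                     if o != sid and math.isfinite(pc_values[o])]
        if not peers_loc or not peers_all:
            continue
        loc_mean = sum(peers_loc) / len(peers_loc)
        all_mean = sum(peers_all) / len(peers_all)
        if loc_mean > 0 and all_mean > 0 and v >= 10 * loc_mean and v >= 10 * all_mean:
            excluded.append(sid)
    retained = {sid: pc_values[sid] for sid in ids if sid not in excluded}
    return retained, excluded


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of P/C against one climate predictor.

    ``signed_r_squared`` carries the sign of the correlation on top of r^2,
    since fingerprinting studies sometimes print signed goodness-of-fit
    values; both r and r^2 are reported to avoid the ambiguity.
    """

    predictor: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    signed_r_squared: float
    p_value: float
    n: int
    excluded: tuple[str, ...] = ()


def fit_pc_vs_climate(
    pc_values: Mapping[str, float],
    metadata: Mapping[str, SiteMetadata],
    predictor: str = "growing_season_d",
    log_response: bool = False,
    excluded: Sequence[str] = (),
) -> RegressionResult:
    """Simple linear regression of P/C on a macroclimate predictor.

    Two-sided p-value for the slope from the t distribution with n-2 degrees
    of freedom.  The response is untransformed P/C by default; a log-P/C
    option is available.
    """
    if predictor not in PREDICTORS:
        raise ValidationError(f"unknown predictor {predictor!r}; pick from {PREDICTORS}")
    xs, ys = [], []
    for sid, pc in pc_values.items():
        if sid not in metadata or not math.isfinite(pc):
            continue
        xs.append(getattr(metadata[sid], predictor))
        ys.append(math.log(pc) if log_response else pc)
    if len(xs) < 3:
        raise ValidationError("need at least three paired observations")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValidationError(f"predictor {predictor!r} has zero variance")
    fit = sps.linregress(x, y)
    r = float(fit.rvalue)
    return RegressionResult(
        predictor=predictor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=r,
        r_squared=r * r,
        signed_r_squared=math.copysign(r * r, r) if r != 0 else 0.0,
        p_value=float(fit.pvalue),
        n=len(xs),
        excluded=tuple(excluded),
    )
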