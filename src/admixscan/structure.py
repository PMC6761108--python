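"""Population-structure tools around the inversion analysis.

Identity-by-state matrices over a region, classical multidimensional
scaling of 1 - IBS, inversion genotyping by a three-component Gaussian
mixture fitted with EM on the leading MDS axis (the invClust approach:
the three clusters along the first axis are the NI/NI, NI/I and I/I
genotypes of a polymorphic inversion), random length-matched control
regions, and Procrustes comparison of ordinations with a permutation
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import RegionInterval, SnpMeta

EM_TOL = 1e-6
EM_MAX_ITER = 1_000_000
N_PERMUTATIONS = 10_000

GENOTYPE_LABELS = ("NI/NI", "NI/I", "I/I")


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

@dataclass
class IbsMatrix:
    values: np.ndarray  # n x n in [0, 1], symmetric, unit diagonal
    n_snps: np.ndarray  # per-pair SNP count used


def ibs_matrix(dosages: np.ndarray) -> IbsMatrix:
    """Pairwise identity-by-state from 0/1/2 dosages.

    IBS(i, j) = mean over SNPs of (2 - |g_i - g_j|) / 2. NaN dosages are
    excluded pairwise; a pair sharing no called SNP is an error.
    """
    g = np.asarray(dosages, dtype=float)
    n, m = g.shape
    if m == 0:
        raise ValueError("no SNPs supplied")
    if not np.isnan(g).any():
        d = squareform(pdist(g, metric="cityblock"))
        vals = 1.0 - d / (2.0 * m)
        counts = np.full((n, n), m)
    else:
        ok = ~np.isnan(g)
        gz = np.nan_to_num(g)
        counts = ok.astype(float) @ ok.T.astype(float)
        if (counts == 0).any():
            raise ValueError("a pair of individuals shares no called SNP")
        # sum |gi - gj| over shared SNPs, via masked broadcast in blocks
        vals = np.empty((n, n))
        for i in range(n):
            diff = np.abs(gz[i] - gz)
            diff[~(ok[i] & ok)] = 0.0
            vals[i] = 1.0 - diff.sum(axis=1) / (2.0 * (ok[i] & ok).sum(axis=1))
        counts = counts.astype(int)
    np.fill_diagonal(vals, 1.0)
    return IbsMatrix(vals, np.asarray(counts))


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

@dataclass
class MdsEmbedding:
    coords: np.ndarray  # n x k_effective
    eigenvalues: np.ndarray  # positive eigenvalues kept, descending
    positive_mass: float  # fraction of positive eigenvalue mass captured


def classical_mds(distances: np.ndarray, k: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) scaling of a distance matrix.

    Squares the distances, double-centers, eigendecomposes, and scales the
    top eigenvectors by the square root of their eigenvalues. Only axes
    with positive eigenvalues are emitted; asking for more returns fewer.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.size else evals > 0
    n_keep = min(k, int(pos.sum()))
    kept = evals[:n_keep]
    coords = evecs[:, :n_keep] * np.sqrt(kept)
    total_pos = evals[pos].sum()
    mass = float(kept.sum() / total_pos) if total_pos > 0 else 0.0
    return MdsEmbedding(coords, kept, mass)


# ---------------------------------------------------------------------------
# EM inversion genotyping
# ---------------------------------------------------------------------------

@dataclass
class InversionGenotypes:
    calls: list[str]  # per individual, one of GENOTYPE_LABELS
    posteriors: np.ndarray  # n x 3, columns ordered (NI/NI, NI/I, I/I)
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: list = field(default_factory=list)
    degenerate: bool = False

    @property
    def dosage(self) -> np.ndarray:
        """Inverted-haplotype count per individual (0, 1, 2)."""
        lut = {lab: i for i, lab in enumerate(GENOTYPE_LABELS)}
        return np.array([lut[c] for c in self.calls])


def _gauss_logpdf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def _run_em(
    x: np.ndarray,
    mus: np.ndarray,
    hwe_tied: bool,
    tol: float,
    max_iter: int,
    var_floor: float,
):
    """One EM run from a fixed start; returns the fitted state and trace."""
    n, d = x.shape
    var = np.full((3, d), x.var(axis=0).mean() + 1e-12)
    w = np.array([0.25, 0.5, 0.25])
    ll_trace: list[float] = []
    converged = False
    degenerate = False
    it = 0
    logpost = np.zeros((n, 3))
    resp = np.full((n, 3), 1.0 / 3)
    while it < max_iter:
        it += 1
        for c in range(3):
            logpost[:, c] = np.log(max(w[c], 1e-300)) + sum(
                _gauss_logpdf(x[:, a], mus[c, a], var[c, a]) for a in range(d)
            )
        mx = logpost.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logpost - mx).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logpost - lse[:, None])
        if ll_trace and abs(ll - ll_trace[-1]) < tol:
            ll_trace.append(ll)
            converged = True
            break
        ll_trace.append(ll)
        nk = resp.sum(axis=0)
        if (nk < 1e-8).any():
            degenerate = True
            break
        for c in range(3):
            mus[c] = (resp[:, c] @ x) / nk[c]
            var[c] = (resp[:, c] @ (x - mus[c]) ** 2) / nk[c]
        var = np.maximum(var, var_floor)
        if hwe_tied:
            # q from the expected inverted-allele dosage under current resp.
            q_hat = (2 * nk[2] + nk[1]) / (2 * n)
            w = np.array([(1 - q_hat) ** 2, 2 * q_hat * (1 - q_hat), q_hat ** 2])
            w = np.maximum(w, 1e-12)
            w /= w.sum()
        else:
            w = nk / n
    return mus, var, w, resp, ll_trace, converged, it, degenerate


def em_inversion_genotypes(
    embedding: MdsEmbedding | np.ndarray,
    axes: int = 1,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    hwe_tied: bool = False,
    anchor_calls: dict[int, str] | None = None,
) -> InversionGenotypes:
    """Three-genotype EM clustering on the leading MDS axis (or axes).

    A three-component Gaussian mixture is fitted by EM on MDS axis 1
    (``axes=2`` uses the first two axes with diagonal covariances).
    Components are ordered by their axis-1 means; the two extreme-mean
    components are the homozygote classes. The higher-weight homozygote
    cluster is labelled NI/NI by default; ``anchor_calls`` (individual
    index -> known genotype label) overrides the orientation.

    ``hwe_tied`` constrains the mixing weights to (q^2, 2q(1-q), (1-q)^2).
    Convergence is declared when the log-likelihood change drops below
    ``tol``; a variance collapse flags the fit degenerate and everyone is
    called NI/NI with full posterior.
    """
    coords = embedding.coords if isinstance(embedding, MdsEmbedding) else np.asarray(embedding, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if n < 6:
        raise ValueError("need at least 6 individuals for three-genotype EM")
    x = coords[:, : max(1, min(axes, coords.shape[1]))]
    spread = x[:, 0].std()
    if spread == 0.0:
        post = np.zeros((n, 3))
        post[:, 0] = 1.0
        return InversionGenotypes(
            ["NI/NI"] * n, post,
            means=np.zeros(3), variances=np.ones(3), weights=np.array([1.0, 0.0, 0.0]),
            converged=True, n_iter=0, log_likelihood=[], degenerate=True,
        )
    d = x.shape[1]
    # deterministic multi-start: quantile-based centre triplets (equal
    # variances, HWE-consistent weights at q = 0.5); the best final
    # log-likelihood wins.  Genotype clusters put the homozygotes at the
    # extremes of axis 1, so extreme-quantile starts matter when one class
    # dominates.
    lo, mid, hi = (np.quantile(x, q, axis=0) for q in (0.02, 0.50, 0.98))
    starts = [
        np.stack([np.quantile(x, q, axis=0) for q in (0.10, 0.50, 0.90)]),
        np.stack([lo, (lo + hi) / 2, hi]),
        np.stack([x.min(axis=0), mid, x.max(axis=0)]),
    ]
    var_floor = 1e-10 * max(spread ** 2, 1e-30)
    best = None
    for mus0 in starts:
        fit = _run_em(x, mus0.copy(), hwe_tied, tol, max_iter, var_floor)
        if best is None or fit[4][-1] > best[4][-1]:
            best = fit
    mus, var, w, resp, ll_trace, converged, it, degenerate = best
    # order components along axis 1
    order = np.argsort(mus[:, 0])
    mus, var, w = mus[order], var[order], w[order]
    resp = resp[:, order]
    # orientation: which extreme component is NI/NI
    flip = w[2] > w[0]
    if anchor_calls:
        votes = 0
        for ind, lab in anchor_calls.items():
            comp = int(np.argmax(resp[ind]))
            if (lab == "NI/NI" and comp == 2) or (lab == "I/I" and comp == 0):
                votes += 1
            elif (lab == "NI/NI" and comp == 0) or (lab == "I/I" and comp == 2):
                votes -= 1
        flip = votes > 0
    if flip:
        mus, var, w = mus[::-1].copy(), var[::-1].copy(), w[::-1].copy()
        resp = resp[:, ::-1]
    calls = [GENOTYPE_LABELS[int(np.argmax(resp[i]))] for i in range(n)]
    return InversionGenotypes(
        calls, resp,
        means=mus[:, 0], variances=var[:, 0], weights=w,
        converged=converged, n_iter=it, log_likelihood=ll_trace,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Random length-matched regions
# ---------------------------------------------------------------------------

def sample_random_regions(
    snps: list[SnpMeta],
    length_bp: int,
    n: int = 7,
    exclude: RegionInterval | None = None,
    seed: int = 0,
    allow_overlap: bool = True,
    max_attempts: int = 10_000,
) -> list[RegionInterval]:
    """Sample regions of exactly ``length_bp``, each within one chromosome.

    Regions avoid ``exclude`` (no overlap); by default they may overlap
    one another. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    extents: dict[str, tuple[int, int]] = {}
    for s in snps:
        lo, hi = extents.get(s.chrom, (s.pos, s.pos))
        extents[s.chrom] = (min(lo, s.pos), max(hi, s.pos))
    chroms = [c for c, (lo, hi) in extents.items() if hi - lo >= length_bp]
    if not chroms:
        raise ValueError("no chromosome long enough for the requested length")
    out: list[RegionInterval] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} regions after {max_attempts} attempts"
            )
        chrom = chroms[rng.integers(len(chroms))]
        lo, hi = extents[chrom]
        start = int(rng.integers(lo, hi - length_bp + 1))
        region = RegionInterval(chrom, start, start + length_bp)
        if exclude is not None and region.chrom == exclude.chrom:
            if region.start_bp <= exclude.end_bp and region.end_bp >= exclude.start_bp:
                continue
        if not allow_overlap and any(
            r.chrom == region.chrom
            and r.start_bp <= region.end_bp
            and r.end_bp >= region.start_bp
            for r in out
        ):
            continue
        out.append(region)
    return out


# ---------------------------------------------------------------------------
# Procrustes comparison with permutation test
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    m_squared: float
    correlation: float
    p_value: float
    n_permutations: int
    rotation: np.ndarray
    scale: float
    translation: np.ndarray


def _procrustes_corr(xc: np.ndarray, yc: np.ndarray, ss_x: float, ss_y: float) -> float:
    svals = np.linalg.svd(xc.T @ yc, compute_uv=False)
    return float(svals.sum() / np.sqrt(ss_x * ss_y))


def procrustes_protest(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
) -> ProcrustesResult:
    """Procrustes superimposition of Y onto X with a permutation test.

    Both configurations are centred; the optimal rotation and uniform
    scaling minimise the residual sum of squares, giving
    m^2 = 1 - (sum of singular values)^2 / (ssX * ssY) and correlation
    sqrt(1 - m^2). The test shuffles rows of Y; the p-value uses the
    add-one estimator (#{perm corr >= observed} + 1) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("configurations must share the row count")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    if x.shape[1] != y.shape[1]:  # pad the narrower configuration with zeros
        k = max(x.shape[1], y.shape[1])
        x = np.pad(x, ((0, 0), (0, k - x.shape[1])))
        y = np.pad(y, ((0, 0), (0, k - y.shape[1])))
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    ss_x = float((xc ** 2).sum())
    ss_y = float((yc ** 2).sum())
    if ss_x == 0 or ss_y == 0:
        raise ValueError("a configuration with zero spread cannot be compared")
    u, svals, vt = np.linalg.svd(xc.T @ yc)
    corr = float(np.clip(svals.sum() / np.sqrt(ss_x * ss_y), 0.0, 1.0))
    m2 = 1.0 - corr ** 2
    rotation = vt.T @ u.T  # maps yc onto xc: yc @ rotation ~ scale * xc
    scale = svals.sum() / ss_y
    translation = mx - scale * (my @ rotation)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = yc[perm]
        if _procrustes_corr(xc, yp, ss_x, ss_y) >= corr - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ProcrustesResult(
        m_squared=max(m2, 0.0),
        correlation=corr,
        p_value=p,
        n_permutations=n_perm,
        rotation=rotation,
        scale=float(scale),
        translation=translation,
    )
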