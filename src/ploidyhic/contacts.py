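"""Contact-matrix container, sparse-triplet IO and matrix balancing.

Balancing finds a positive diagonal scaling D such that every row of D·M·D sums
to 1 (a doubly stochastic scaling of the symmetric map), which removes per-bin
coverage bias.  The primary solver is the Knight–Ruiz inner–outer Newton
iteration; a Sinkhorn (iterative proportional fitting) fallback is provided and
used automatically if Newton fails to converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout

RAW = "raw"
BALANCED = "balanced"


@dataclass
class ContactMatrix:
    """Symmetric genome-wide binned contact map for one condition/replicate.

    ``mask`` marks usable bins (True); bins with zero (or sub-threshold) raw
    marginals are masked out before balancing and stay masked downstream.
    """

    layout: GenomeLayout
    matrix: np.ndarray
    state: str = RAW
    mask: np.ndarray | None = None
    balancing_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.layout.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match layout ({n} bins)"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite entries")
        if np.any(self.matrix < 0):
            raise ValueError("matrix contains negative entries")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix is not symmetric")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)

    @property
    def total_contacts(self) -> float:
        return float(np.triu(self.matrix).sum())

    def cis_mask(self) -> np.ndarray:
        """Boolean (n,n) matrix: True where both bins on the same chromosome."""
        ci = self.layout.bin_chrom_index()
        return ci[:, None] == ci[None, :]


# -- IO --------------------------------------------------------------------

_TRIPLET_COLS = ["chromA", "startA", "chromB", "startB", "count"]


def read_triplets(path: str | Path, layout: GenomeLayout) -> ContactMatrix:
    """Read a 5-column sparse triplet TSV (chromA, startA, chromB, startB, count).

    Positions must lie on the bin grid; duplicate (i,j)/(j,i) rows are summed.
    """
    n = layout.n_bins
    M = np.zeros((n, n))
    offsets = layout.chrom_offsets()
    lengths = layout.chrom_lengths
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            ca, sa, cb, sb, cnt = (
                parts[0], int(parts[1]), parts[2], int(parts[3]), float(parts[4]),
            )
            for c in (ca, cb):
                if c not in lengths:
                    raise ValueError(f"row {lineno}: unknown chromosome {c!r}")
            for c, s in ((ca, sa), (cb, sb)):
                if s % layout.bin_size != 0:
                    raise ValueError(
                        f"row {lineno}: position {c}:{s} not on the "
                        f"{layout.bin_size}-bp bin grid"
                    )
                if not (0 <= s < lengths[c]):
                    raise ValueError(f"row {lineno}: position {c}:{s} out of range")
            i = offsets[ca] + sa // layout.bin_size
            j = offsets[cb] + sb // layout.bin_size
            M[i, j] += cnt
            if i != j:
                M[j, i] += cnt
            n_rows += 1
    if n_rows == 0:
        warnings.warn(f"{path}: no contact rows found; matrix is all zero")
    return ContactMatrix(layout, M, state=RAW)


def write_triplets(cm: ContactMatrix, path: str | Path) -> None:
    """Write upper-triangle non-zero entries as a 5-column triplet TSV."""
    layout = cm.layout
    names = layout.chrom_names
    ci = layout.bin_chrom_index()
    starts = np.empty(layout.n_bins, dtype=np.int64)
    for name in names:
        off = layout.chrom_offsets()[name]
        k = layout.n_bins_of(name)
        starts[off : off + k] = np.arange(k) * layout.bin_size
    iu, ju = np.triu_indices(layout.n_bins)
    vals = cm.matrix[iu, ju]
    keep = vals != 0
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TRIPLET_COLS) + "\n")
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            v_out = int(v) if float(v).is_integer() else repr(float(v))
            fh.write(
                f"{names[ci[i]]}\t{starts[i]}\t{names[ci[j]]}\t{starts[j]}\t{v_out}\n"
            )


# -- balancing -------------------------------------------------------------


def _kr_vector(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Knight–Ruiz scaling vector x with x*(A@x) = 1, or None on failure.

    Inner–outer Newton iteration with conjugate-gradient inner solves, following
    the standard algorithm for symmetric nonnegative matrices.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rold = rho_km1
    i = 0
    while rout > rt:
        i += 1
        if i > max_iter:
            return None
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            if k > 10 * n + 50:
                return None
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0 or not np.isfinite(denom):
                return None
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                if not ind.any():
                    break
                gamma = float(((delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = float(((Delta - y[ind]) / ap[ind]).min())
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
        x = x * y
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            return None
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def _sinkhorn_vector(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Sinkhorn/IPF scaling vector for a symmetric matrix (slower, very robust)."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        s = A @ x
        if np.any(s <= 0):
            return None
        x = np.sqrt(x / s)  # damped symmetric update; fixed point has x*(Ax)=1
        resid = np.abs(x * (A @ x) - 1.0).max()
        if resid < tol:
            return x
    return None


def kr_balance(
    cm: ContactMatrix,
    tol: float = 1e-10,
    max_iter: int = 200,
    min_marginal: float = 0.0,
    method: str = "kr",
) -> ContactMatrix:
    """Balance a raw contact map so every unmasked row sums to 1.

    Bins whose raw marginal is <= ``min_marginal`` (default: exactly zero) are
    masked out before balancing and remain zero.  Raises if neither the
    Knight–Ruiz iteration nor the Sinkhorn fallback converges.
    """
    if cm.state != RAW:
        raise ValueError("kr_balance expects a raw matrix")
    n = cm.layout.n_bins
    marg = cm.matrix.sum(axis=1)
    mask = cm.mask & (marg > min_marginal)
    if not mask.any():
        raise ValueError("all bins masked; nothing to balance")
    A = cm.matrix[np.ix_(mask, mask)]
    # scale-invariance guard: normalize to O(1) entries before iterating
    scale = A.sum() / A.shape[0]
    A_s = A / scale

    x = None
    if method == "kr":
        x = _kr_vector(A_s, tol=min(tol, 1e-12), max_iter=max_iter)
    if x is None or method == "sinkhorn":
        x = _sinkhorn_vector(A_s, tol=min(tol, 1e-12), max_iter=max(max_iter * 50, 5000))
    if x is None:
        resid = np.abs(A_s.sum(axis=1) - 1.0).max()
        raise RuntimeError(
            f"matrix balancing failed to converge after {max_iter} outer iterations "
            f"(unbalanced residual {resid:.3g}); matrix may lack total support"
        )
    x = x / np.sqrt(scale)
    B_sub = (x[:, None] * A) * x[None, :]
    rows = B_sub.sum(axis=1)
    if np.abs(rows - 1.0).max() > max(tol, 1e-8):
        raise RuntimeError(
            f"balancing residual {np.abs(rows - 1.0).max():.3g} exceeds tolerance"
        )
    B = np.zeros((n, n))
    B[np.ix_(mask, mask)] = B_sub
    bv = np.zeros(n)
    bv[mask] = x
    return ContactMatrix(cm.layout, B, state=BALANCED, mask=mask, balancing_vector=bv)


# -- replicate reproducibility --------------------------------------------


def replicate_correlation(m1: ContactMatrix, m2: ContactMatrix) -> float:
    """Pearson correlation of two maps over upper-triangle entries (incl. diagonal).

    Entries whose bins are masked in both matrices are excluded.  Raises on
    zero variance.
    """
    if m1.layout.n_bins != m2.layout.n_bins:
        raise ValueError("matrices have different layouts")
    if m1.state != m2.state:
        raise ValueError("compare raw with raw or balanced with balanced")
    n = m1.layout.n_bins
    iu, ju = np.triu_indices(n)
    ok1 = m1.mask[iu] & m1.mask[ju]
    ok2 = m2.mask[iu] & m2.mask[ju]
    keep = ok1 | ok2
    x = m1.matrix[iu, ju][keep]
    y = m2.matrix[iu, ju][keep]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a matrix; Pearson correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def downsample_to_match(
    a: ContactMatrix, b: ContactMatrix, seed: int
) -> tuple[ContactMatrix, ContactMatrix]:
    """Binomially thin the deeper raw map to the shallower map's total contacts.

    Matches sequencing depth between conditions before balancing, so that the
    difference matrix compares maps at equal depth.
    """
    if a.state != RAW or b.state != RAW:
        raise ValueError("downsampling applies to raw count matrices")
    ta, tb = a.total_contacts, b.total_contacts
    if ta == tb:
        return a, b
    hi, lo = (a, b) if ta > tb else (b, a)
    p = lo.total_contacts / hi.total_contacts
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(hi.layout.n_bins)
    vals = hi.matrix[iu, ju]
    thinned = np.zeros_like(vals)
    nz = vals > 0
    thinned[nz] = rng.binomial(vals[nz].astype(np.int64), p)
    M = np.zeros_like(hi.matrix)
    M[iu, ju] = thinned
    M[ju, iu] = thinned
    hi_new = ContactMatrix(hi.layout, M, state=RAW, mask=hi.mask.copy())
    return (hi_new, lo) if ta > tb else (lo, hi_new)
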