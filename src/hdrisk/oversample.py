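"""Minority-class oversampling with correlated Gaussian noise.

The generator used to balance the symptomatic class works in three steps:

1. screen each variable for normality (one-sample Kolmogorov-Smirnov
   against a normal with the sample's own mean/SD; failures warn),
2. draw independent standard-normal rows and induce the target pairwise
   correlations through a triangular transform — for two variables
   ``u' = u*sqrt(1 - rho^2) + v*rho,  v' = v``; for the full variable set
   the lower-triangular (Cholesky) factor of the repaired correlation
   matrix, which reduces to the pair transform when only two variables are
   involved,
3. restore native units via ``x' = mu + k*sigma*z`` where ``k`` scales the
   injected noise's standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import SessionRecord

logger = logging.getLogger(__name__)

#: canonical variable order for session-level oversampling: weights, SBPs,
#: DBPs, HRs by timepoint, then the prescription fields.
SESSION_VARIABLES = (
    [f"weight_t{j}" for j in range(9)]
    + [f"sbp_t{j}" for j in range(9)]
    + [f"dbp_t{j}" for j in range(9)]
    + [f"hr_t{j}" for j in range(9)]
    + ["dry_weight", "target_end_weight", "hourly_weight_loss", "prev_end_weight"]
)


def balance_count(n_majority: int, n_minority: int) -> int:
    """Number of synthetic minority rows needed to balance the classes."""
    if n_minority < 0 or n_majority < 0:
        raise ValueError("counts must be nonnegative")
    if n_minority > n_majority:
        raise ValueError(
            f"minority count ({n_minority}) exceeds majority count ({n_majority})"
        )
    return n_majority - n_minority


def correlate_pair(u: np.ndarray, v: np.ndarray, rho: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Correlate two standard-score vectors: ``u' = u*sqrt(1-rho^2) + v*rho``.

    ``v`` is returned unchanged.  For independent zero-mean unit-variance
    inputs, ``u'`` keeps zero mean and unit variance and corr(u', v') = rho.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("u and v must have the same shape")
    if abs(rho) > 1:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    return u * np.sqrt(1.0 - rho ** 2) + v * rho, v.copy()


def scale_shift(z: np.ndarray, mu: float, sigma: float, k: float = 1.0) -> np.ndarray:
    """Map standard scores to native units: ``mu + k*sigma*z``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    return mu + k * sigma * np.asarray(z, float)


def nearest_correlation(corr: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix into a positive-definite correlation matrix.

    Eigenvalues are clipped at ``min_eig`` and the result renormalized to a
    unit diagonal.  Small-sample (or hand-assembled) correlation matrices
    are routinely rank-deficient; this is the minimal fix that keeps the
    triangular factorization well defined.
    """
    c = np.asarray(corr, float)
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < min_eig:
        vals = np.clip(vals, min_eig, None)
        c = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
    return c


def induce_correlations(z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Transform independent standard-normal rows to the target correlations.

    ``z`` is (n, d); the repaired correlation matrix's lower Cholesky factor
    is applied to each row.  With variables ordered (v, u) this reduces
    exactly to the two-variable transform of :func:`correlate_pair`.
    """
    z = np.asarray(z, float)
    c = nearest_correlation(np.asarray(corr, float))
    if c.shape != (z.shape[1], z.shape[1]):
        raise ValueError("corr shape does not match number of columns")
    length = np.linalg.cholesky(c)
    return z @ length.T


def normality_screen(samples: Mapping[str, Sequence[float]], alpha: float = 0.01
                     ) -> pd.DataFrame:
    """One-sample KS test of each variable against its own fitted normal.

    Returns a frame with columns ``variable, n, statistic, p, passed``
    (``passed`` iff p >= alpha).  Failures are reported with a warning but
    are non-fatal.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for name, values in samples.items():
        x = np.asarray(values, float)
        if x.size < 5:
            raise InsufficientDataError(
                f"{name}: need >= 5 observations for the KS screen, got {x.size}"
            )
        mu, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            rows.append((name, x.size, np.nan, 0.0, False))
            continue
        stat, p = stats.kstest(x, "norm", args=(mu, sd))
        rows.append((name, x.size, stat, p, p >= alpha))
    report = pd.DataFrame(rows, columns=["variable", "n", "statistic", "p", "passed"])
    failed = report.loc[~report["passed"], "variable"].tolist()
    if failed:
        warnings.warn(
            f"normality screen failed at alpha={alpha} for: {', '.join(failed)}",
            stacklevel=2,
        )
    return report


@dataclass
class OversampleSpec:
    """Moments and correlation targets estimated from the minority sample."""

    variable_names: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    corr: np.ndarray
    n_new: int
    k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        self.corr = np.asarray(self.corr, float)
        d = len(self.variable_names)
        if self.mu.shape != (d,) or self.sigma.shape != (d,):
            raise ValueError("mu/sigma length must match variable_names")
        if self.corr.shape != (d, d):
            raise ValueError("corr must be square and match variable_names")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigmas must be > 0")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if self.n_new < 0:
            raise ValueError("n_new must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")


def generate_rows(spec: OversampleSpec) -> pd.DataFrame:
    """Draw ``spec.n_new`` synthetic rows with the spec's moments/correlations."""
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_new, len(spec.variable_names)))
    zc = induce_correlations(z, spec.corr) if spec.n_new else z
    x = spec.mu + spec.k * spec.sigma * zc
    return pd.DataFrame(x, columns=spec.variable_names)


def estimate_spec(frame: pd.DataFrame, n_new: int, k: float = 1.0, seed: int = 0,
                  min_sigma: float = 1e-9) -> OversampleSpec:
    """Estimate an :class:`OversampleSpec` from an observed sample frame.

    Constant columns get a floor SD of ``min_sigma`` (they are reproduced
    as constants); undefined correlation entries are treated as zero.
    """
    if len(frame) < 3:
        raise InsufficientDataError(
            f"need >= 3 rows to estimate moments/correlations, got {len(frame)}"
        )
    x = frame.to_numpy(float)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    sigma = np.where(sigma > 0, sigma, min_sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return OversampleSpec(list(frame.columns), mu, sigma, corr, n_new, k, seed)


def sessions_to_frame(sessions: Sequence["SessionRecord"]) -> pd.DataFrame:
    """Flatten sessions into the canonical oversampling variable frame."""
    rows = [
        np.concatenate([
            s.weight, s.sbp, s.dbp, s.hr,
            [s.dry_weight, s.target_end_weight, s.hourly_weight_loss,
             s.prev_end_weight],
        ])
        for s in sessions
    ]
    return pd.DataFrame(rows, columns=SESSION_VARIABLES)


def oversample_sessions(symptomatic: Sequence["SessionRecord"], n_new: int,
                        k: float = 1.0, seed: int = 0) -> list["SessionRecord"]:
    """Generate ``n_new`` synthetic symptomatic sessions.

    Moments and the full pairwise correlation matrix are estimated from the
    supplied symptomatic sample over all grid vitals and prescription
    fields.  Synthetic records are flagged ``is_synthetic`` and receive an
    onset index resampled from the estimation sample's onset distribution.
    """
    from .cohort import SessionRecord  # local import to avoid a cycle

    if len(symptomatic) < 3:
        raise InsufficientDataError(
            f"need >= 3 symptomatic sessions, got {len(symptomatic)}"
        )
    if not all(s.symptomatic for s in symptomatic):
        raise ValueError("estimation sample must be all symptomatic")
    if n_new == 0:
        return []

    spec = estimate_spec(sessions_to_frame(symptomatic), n_new=n_new, k=k, seed=seed)
    frame = generate_rows(spec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    onsets = np.array([s.onset_index for s in symptomatic], int)
    new_onsets = rng.choice(onsets, size=n_new, replace=True)

    x = frame.to_numpy(float)
    out = []
    for i in range(n_new):
        row = x[i]
        out.append(SessionRecord(
            patient_id="synthetic",
            session_id=f"synth-{seed}-{i:05d}",
            weight=np.maximum(row[0:9], 1e-3),
            sbp=np.maximum(row[9:18], 1e-3),
            dbp=np.maximum(row[18:27], 1e-3),
            hr=np.maximum(row[27:36], 1e-3),
            dry_weight=max(float(row[36]), 1e-3),
            target_end_weight=float(row[37]),
            hourly_weight_loss=float(row[38]),
            prev_end_weight=float(row[39]),
            symptomatic=True,
            onset_index=int(new_onsets[i]),
            is_synthetic=True,
        ))
    logger.debug("oversampled %d synthetic sessions (k=%g)", n_new, k)
    return out
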