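"""Phonon-map quantification: Brillouin formulas, two-component Gaussian
mixture segmentation, Mahalanobis confidence regions and Yuen's t-test.

The mixture is fitted by expectation-maximization written out explicitly so
the log-likelihood trajectory is available and its monotonicity can be
asserted.  Initialization is 2-means on standardized coordinates; the
component with the higher mean frequency shift is labelled ``cell wall``
(the stiffer phase), overridable by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, t as t_dist
from sklearn.cluster import KMeans

__all__ = [
    "PhononParams",
    "PhononMap",
    "Gmm2",
    "brillouin_shift",
    "longitudinal_modulus",
    "fit_gmm2",
    "mahalanobis_sq",
    "confidence_membership",
    "yuen_test",
    "YuenResult",
]


@dataclass
class PhononParams:
    """Optical / acoustic constants: refractive index, sound velocity
    (m/s), probe wavelength (m) and mass density (kg/m^3)."""

    n: float = 1.5
    v: float = 1500.0
    lambda_probe: float = 780e-9
    rho: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("n", "v", "lambda_probe", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def brillouin_shift(params: PhononParams) -> float:
    """Brillouin frequency shift f_B = 2 n v / lambda_probe (Hz)."""
    return 2.0 * params.n * params.v / params.lambda_probe


def longitudinal_modulus(params: PhononParams) -> float:
    """Longitudinal elastic modulus M = rho v^2 (Pa)."""
    return params.rho * params.v ** 2


# ----------------------------------------------------------------------
@dataclass
class PhononMap:
    """Rectangular pixel grid of (frequency shift, attenuation) values."""

    dfb: np.ndarray  # GHz, 2-D
    ab: np.ndarray   # arbitrary units, same shape
    truth: np.ndarray = None  # optional component labels, same shape

    def __post_init__(self) -> None:
        self.dfb = np.asarray(self.dfb, dtype=float)
        self.ab = np.asarray(self.ab, dtype=float)
        if self.dfb.ndim != 2 or self.dfb.shape != self.ab.shape:
            raise ValueError("dfb and ab must be 2-D arrays of equal shape")
        if not (np.all(np.isfinite(self.dfb)) and np.all(np.isfinite(self.ab))):
            raise ValueError("map values must be finite")

    @property
    def shape(self):
        return self.dfb.shape

    def stack(self) -> np.ndarray:
        """Pixels as an (n, 2) array of (dfb, ab)."""
        return np.column_stack([self.dfb.ravel(), self.ab.ravel()])


@dataclass
class Gmm2:
    """Fitted two-component bivariate Gaussian mixture over a pixel map."""

    weights: np.ndarray        # (2,)
    means: np.ndarray          # (2, 2)
    covs: np.ndarray           # (2, 2, 2)
    loglik: float
    loglik_path: np.ndarray
    resp: np.ndarray           # (n, 2) responsibilities
    data: np.ndarray           # (n, 2) the fitted pixels
    labels: dict = field(default_factory=dict)  # comp index -> name

    def __post_init__(self) -> None:
        if not np.all((self.weights > 0) & (self.weights < 1)):
            raise ValueError("weights must lie in (0, 1)")
        if not np.allclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        for c in self.covs:
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be positive definite")
        if not np.allclose(self.resp.sum(axis=1), 1.0):
            raise ValueError("responsibility rows must sum to 1")

    def assignments(self) -> np.ndarray:
        return np.argmax(self.resp, axis=1)


def _gauss2_logpdf(X, mean, cov):
    d = X - mean[None, :]
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
    maha = np.einsum("ni,ij,nj->n", d, inv, d)
    return -0.5 * (maha + np.log(det) + 2.0 * np.log(2.0 * np.pi))


def fit_gmm2(
    pmap: PhononMap,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> Gmm2:
    """EM fit of a two-component bivariate Gaussian mixture.

    The log-likelihood is non-decreasing at every iteration (asserted).
    Covariance collapse triggers diagonal regularization restarts; repeated
    failure raises.  The component with higher mean frequency shift is
    labelled ``cell wall``, the other ``background``.
    """
    X = pmap.stack()
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 pixels")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate map: no spread in either channel")

    Z = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
    lab = km.labels_

    base_reg = 1e-10 * float(np.trace(np.cov(X.T)) / 2.0 + 1e-30)
    for attempt in range(6):
        reg = base_reg * (10.0 ** (2 * attempt))
        try:
            return _em_run(X, lab, reg, tol, max_iter)
        except np.linalg.LinAlgError:
            continue
        except FloatingPointError:
            continue
    raise RuntimeError("GMM fit failed: covariance collapse despite regularization")


def _em_run(X, init_labels, reg, tol, max_iter) -> Gmm2:
    n = X.shape[0]
    weights = np.empty(2)
    means = np.empty((2, 2))
    covs = np.empty((2, 2, 2))
    for k in range(2):
        mask = init_labels == k
        if mask.sum() < 2:
            mask = np.zeros(n, dtype=bool)
            mask[k::2] = True
        weights[k] = mask.mean()
        means[k] = X[mask].mean(axis=0)
        covs[k] = np.cov(X[mask].T) + reg * np.eye(2)
    weights = np.clip(weights, 1e-10, 1 - 1e-10)
    weights /= weights.sum()

    ll_path = []
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.column_stack(
            [np.log(weights[k]) + _gauss2_logpdf(X, means[k], covs[k])
             for k in range(2)]
        )
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        if ll_path and ll < ll_path[-1] - 1e-7 * max(1.0, abs(ll_path[-1])):
            raise AssertionError("EM log-likelihood decreased")
        ll_path.append(ll)
        resp = np.exp(logp - norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            nk = np.maximum(nk, 1e-8)
        weights = np.clip(nk / n, 1e-10, 1 - 1e-10)
        weights /= weights.sum()
        for k in range(2):
            means[k] = resp[:, k] @ X / nk[k]
            d = X - means[k][None, :]
            covs[k] = (resp[:, k][:, None] * d).T @ d / nk[k] + reg * np.eye(2)
            if np.any(np.linalg.eigvalsh(covs[k]) <= 0):
                raise np.linalg.LinAlgError("covariance collapse")
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll

    wall = int(np.argmax(means[:, 0]))  # higher mean frequency shift
    labels = {wall: "cell wall", 1 - wall: "background"}
    return Gmm2(
        weights=weights,
        means=means,
        covs=covs,
        loglik=prev,
        loglik_path=np.asarray(ll_path),
        resp=resp,
        data=X,
        labels=labels,
    )


# ----------------------------------------------------------------------
def mahalanobis_sq(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of rows of X from (mean, cov)."""
    d = np.asarray(X, dtype=float) - np.asarray(mean, dtype=float)[None, :]
    inv = np.linalg.inv(np.asarray(cov, dtype=float))
    return np.einsum("ni,ij,nj->n", d, inv, d)


def confidence_membership(gmm: Gmm2, level: float = 0.70):
    """Confidence-region masks and per-region channel means.

    A pixel belongs to a component's region iff it is assigned to that
    component by maximum responsibility AND its squared Mahalanobis
    distance is within the chi-square(2) quantile at ``level``.  Returns
    ``(masks, means)`` where ``masks`` is an (n, 2) boolean array and
    ``means`` maps component name -> (mean dfb, mean ab) or None for an
    empty region.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    q = np.inf if level == 1.0 else chi2.ppf(level, df=2)
    assign = gmm.assignments()
    masks = np.zeros((gmm.data.shape[0], 2), dtype=bool)
    means = {}
    for k in range(2):
        m2 = mahalanobis_sq(gmm.data, gmm.means[k], gmm.covs[k])
        masks[:, k] = (assign == k) & (m2 <= q)
        name = gmm.labels.get(k, f"component{k}")
        if masks[:, k].any():
            sub = gmm.data[masks[:, k]]
            means[name] = (float(sub[:, 0].mean()), float(sub[:, 1].mean()))
        else:
            means[name] = None
    return masks, means


# ----------------------------------------------------------------------
@dataclass
class YuenResult:
    t: float
    df: float
    p: float
    one_sided: bool
    trim: float


def _trimmed_stats(x: np.ndarray, trim: float):
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    g = int(np.floor(trim * n))
    h = n - 2 * g
    if h < 2:
        raise ValueError(f"over-trimming: {h} values left of {n}")
    tmean = x[g:n - g].mean()
    xw = x.copy()
    xw[:g] = x[g]
    xw[n - g:] = x[n - g - 1]
    winvar = xw.var(ddof=1)
    return tmean, winvar, n, h


def yuen_test(
    x, y, trim: float = 0.2, one_sided: bool = False
) -> YuenResult:
    """Yuen's t-test on trimmed means with winsorized variances.

    With ``trim=0`` this reduces exactly to Welch's t-test.  Two-sided p by
    default; the one-sided alternative is "x has larger trimmed mean".
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    mx, vx, nx, hx = _trimmed_stats(x, trim)
    my, vy, ny, hy = _trimmed_stats(y, trim)
    dx = (nx - 1) * vx / (hx * (hx - 1))
    dy = (ny - 1) * vy / (hy * (hy - 1))
    se = np.sqrt(dx + dy)
    if se == 0:
        tstat = 0.0
        df = hx + hy - 2.0
    else:
        tstat = (mx - my) / se
        df = (dx + dy) ** 2 / (dx**2 / (hx - 1) + dy**2 / (hy - 1))
    if one_sided:
        p = float(t_dist.sf(tstat, df))
    else:
        p = float(2.0 * t_dist.sf(abs(tstat), df))
    return YuenResult(t=float(tstat), df=float(df), p=min(p, 1.0),
                      one_sided=one_sided, trim=trim)
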