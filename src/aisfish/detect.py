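"""Fishing-activity detection from per-vessel speed profiles.

A trawler's speed-over-ground histogram is bimodal: a slow mode while
towing gear and a fast mode while steaming.  Each vessel's cleaned speeds
are modelled as a two-component Gaussian mixture

    f(v) = pi * N(v; mu1, sigma1^2) + (1 - pi) * N(v; mu2, sigma2^2),

fitted by expectation-maximization, with components ordered so mu1 < mu2.
A message is classified as fishing when its speed falls inside
[mu1 - k*sigma1, mu1 + k*sigma1] (k = 1.5 by default), the confidence band
around the slow mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

SIGMA_FLOOR = 0.05  # knots; guards the degenerate-likelihood spike
DEFAULT_K_SD = 1.5


class InsufficientDataError(ValueError):
    """Fewer than 4 speed observations."""


class DegenerateDataError(ValueError):
    """All speed observations identical."""


@dataclass
class SpeedProfileModel:
    """Fitted two-Gaussian speed mixture for one vessel.

    ``mu1``/``sigma1`` describe the slow (fishing) mode and ``mu2``/
    ``sigma2`` the fast (steaming) mode, in knots; ``pi`` is the weight of
    the slow mode.  ``bimodal`` is False when |mu2 - mu1| <
    2*max(sigma1, sigma2), i.e. when the two modes overlap so much that a
    speed-only classification is doubtful; classification still proceeds
    but the flag propagates to reports.
    """

    pi: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int
    k_sd: float = DEFAULT_K_SD
    loglik_path: list[float] = field(default_factory=list, repr=False)

    @property
    def bimodal(self) -> bool:
        return abs(self.mu2 - self.mu1) >= 2.0 * max(self.sigma1, self.sigma2)

    @property
    def interval(self) -> tuple[float, float]:
        return fishing_interval(self, self.k_sd)


def _log_norm_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def _em(x: np.ndarray, pi: float, mu: np.ndarray, sigma: np.ndarray,
        tol: float, max_iter: int) -> tuple:
    """Run EM from one start; returns (pi, mu, sigma, loglik, converged, it, path)."""
    n = x.size
    w = np.array([pi, 1 - pi])
    ll_old = -np.inf
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: ownership probability of each observation for each component
        logp = np.stack([np.log(w[k]) + _log_norm_pdf(x, mu[k], sigma[k])
                         for k in range(2)])
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        path.append(ll)
        resp = np.exp(logp - norm)
        # M-step: weighted moments
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp @ x) / nk
        var = np.einsum("kn,kn->k", resp, (x[None, :] - mu[:, None]) ** 2) / nk
        sigma = np.maximum(np.sqrt(var), SIGMA_FLOOR)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return float(w[0]), mu, sigma, ll, converged, it, path


def fit_speed_mixture(speeds, tol: float = 1e-8, max_iter: int = 1000,
                      n_restarts: int = 3, seed: int | None = None
                      ) -> SpeedProfileModel:
    """Fit the two-component speed mixture by EM, best of ``n_restarts``.

    The first start places the means at the 25th/75th speed percentiles
    with half the sample SD and equal weights; the remaining starts use
    random responsibilities.  Components are sorted so mu1 < mu2.
    """
    x = np.asarray(speeds, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 speeds, got {x.size}")
    if np.unique(x).size < 2:
        raise DegenerateDataError("all speed values identical")
    rng = np.random.default_rng(seed)

    sd = float(np.std(x))
    starts = [(0.5, np.percentile(x, [25, 75]).astype(float),
               np.full(2, max(sd / 2, SIGMA_FLOOR)))]
    for _ in range(max(0, n_restarts - 1)):
        r = rng.random(x.size)
        resp = np.stack([r, 1 - r])
        nk = resp.sum(axis=1)
        mu0 = (resp @ x) / nk
        var0 = np.einsum("kn,kn->k", resp, (x[None, :] - mu0[:, None]) ** 2) / nk
        starts.append((float(nk[0] / x.size), mu0,
                       np.maximum(np.sqrt(var0), SIGMA_FLOOR)))

    best = None
    for pi0, mu0, sigma0 in starts:
        fit = _em(x, pi0, mu0.copy(), sigma0.copy(), tol, max_iter)
        if best is None or fit[3] > best[3]:
            best = fit
    pi, mu, sigma, ll, converged, it, path = best
    if mu[0] > mu[1]:
        mu, sigma, pi = mu[::-1], sigma[::-1], 1 - pi
    return SpeedProfileModel(pi=float(pi), mu1=float(mu[0]), sigma1=float(sigma[0]),
                             mu2=float(mu[1]), sigma2=float(sigma[1]), loglik=ll,
                             n_obs=int(x.size), converged=converged, n_iter=it,
                             loglik_path=path)


def fishing_interval(model: SpeedProfileModel, k_sd: float = DEFAULT_K_SD
                     ) -> tuple[float, float]:
    """Fishing-speed interval [mu1 - k*sigma1, mu1 + k*sigma1], floored at 0."""
    lo = max(0.0, model.mu1 - k_sd * model.sigma1)
    hi = model.mu1 + k_sd * model.sigma1
    return lo, hi


def classify_messages(messages: pd.DataFrame, model: SpeedProfileModel,
                      k_sd: float = DEFAULT_K_SD) -> pd.DataFrame:
    """Label each message fishing/non-fishing by the model's speed interval.

    The interval is closed on both ends.  Raises if the model did not
    converge — such vessels are unclassifiable.
    """
    if not model.converged:
        raise ValueError("model did not converge; vessel unclassifiable")
    out = messages.copy()
    lo, hi = fishing_interval(model, k_sd)
    sp = out["speed"]
    out["label"] = np.where((sp >= lo) & (sp <= hi), "fishing", "non-fishing")
    return out


def fit_and_classify_fleet(messages: pd.DataFrame, k_sd: float = DEFAULT_K_SD,
                           seed: int | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-vessel fit + classification over a cleaned multi-vessel table.

    Returns (labeled messages, per-vessel model parameter table).  Vessels
    whose fit fails or does not converge are dropped from the labeled
    output and flagged in the parameter table.
    """
    labeled, params = [], []
    for k, (vessel, grp) in enumerate(messages.groupby("ais_vessel_id")):
        row = dict(ais_vessel_id=vessel, n_obs=len(grp))
        try:
            m = fit_speed_mixture(grp["speed"],
                                  seed=None if seed is None else seed + k)
        except (InsufficientDataError, DegenerateDataError) as e:
            params.append(row | dict(status=type(e).__name__))
            continue
        lo, hi = fishing_interval(m, k_sd)
        row |= dict(pi=m.pi, mu1=m.mu1, sigma1=m.sigma1, mu2=m.mu2,
                    sigma2=m.sigma2, loglik=m.loglik, converged=m.converged,
                    bimodal=m.bimodal, lo=lo, hi=hi,
                    status="ok" if m.converged else "not-converged")
        params.append(row)
        if m.converged:
            labeled.append(classify_messages(grp, m, k_sd))
    out = (pd.concat(labeled, ignore_index=True) if labeled
           else messages.iloc[0:0].assign(label=pd.Series(dtype=str)))
    return out, pd.DataFrame(params)
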