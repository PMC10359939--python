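"""Imaging-screen readouts and mixture-model hit calling.

A treated well's survival fraction (SF) is its nuclei count divided by the
mean DMSO-well count on the same plate; z-scores express SF in units of
the DMSO wells' spread.  Compound activity over the dose range is
summarised by a trapezoidal AUC on log10 concentration, normalised by the
log-concentration span so a flat SF = c profile gives AUC = c.

Hit calling is data driven: for each (patient, concentration) the pooled
treated readouts are modelled as a two-component Gaussian mixture — one
background component (inactive compounds, SF near 1) and one freely
estimated component for extreme responses.  The activity threshold is an
extreme lower quantile (default the 0.01th percentile, i.e. tail
probability 1e-4) of the fitted background Gaussian; a compound is a
strong hit for a patient when its readout falls strictly below the
threshold at every tested concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .core_io import ScreenConfig, ScreenPlateSet, ValidationError, logger


# ---------------------------------------------------------------------------
# Per-well readouts
# ---------------------------------------------------------------------------

def survival_fraction(plates: ScreenPlateSet) -> pd.DataFrame:
    """Append an ``sf`` column: nuclei count / plate DMSO-mean count."""
    df = plates.df.copy()
    dmso_mean = (df[df["role"] == "dmso"]
                 .groupby("plate_id")["nuclei_count"].mean())
    zero = dmso_mean[dmso_mean <= 0]
    if not zero.empty:
        raise ValidationError(
            f"plates with zero mean DMSO nuclei count: {list(zero.index)}")
    df["sf"] = df["nuclei_count"] / df["plate_id"].map(dmso_mean)
    return df


def sf_zscore(plates: ScreenPlateSet) -> pd.DataFrame:
    """Append a ``zscore`` column: (SF - mean SF_dmso) / sd SF_dmso per plate.

    Plates with fewer than two DMSO wells or zero DMSO spread get missing
    z-scores (with a warning) — the normalisation is undefined there.
    """
    df = survival_fraction(plates)
    dmso = df[df["role"] == "dmso"].groupby("plate_id")["sf"]
    mean = dmso.mean()
    sd = dmso.std(ddof=1)  # NaN for single-well plates
    bad = sd.index[sd.isna() | (sd == 0)].tolist()
    if bad:
        logger.warning("z-score undefined on plates %s (needs >=2 DMSO wells "
                       "with nonzero spread)", bad)
        sd = sd.replace(0, np.nan)
    df["zscore"] = (df["sf"] - df["plate_id"].map(mean)) / df["plate_id"].map(sd)
    return df


def dose_auc(sf_values: Sequence[float],
             concentrations_nM: Sequence[float]) -> float:
    """Normalised trapezoidal AUC of SF over log10 concentration.

    Dividing the trapezoid area by the log-concentration span keeps the AUC
    on the SF scale (constant SF = c → AUC = c); lower AUC = more active.
    """
    y = np.asarray(sf_values, dtype=float)
    x = np.log10(np.asarray(concentrations_nM, dtype=float))
    if y.shape != x.shape or len(y) < 2:
        raise ValidationError("need an SF value for every concentration (>=2)")
    if np.isnan(y).any():
        raise ValidationError("missing SF dose(s) in profile")
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def build_profiles(plates: ScreenPlateSet,
                   config: ScreenConfig | None = None) -> pd.DataFrame:
    """Per (patient, compound) dose-response profiles with SF, z-score, AUC.

    Replicate treated wells at the same dose are averaged.  Returns a long
    table (patient_id, compound_id, concentration_nM, sf, zscore) joined
    with a per-profile ``auc`` computed on the configured concentrations.
    """
    config = config or ScreenConfig()
    df = sf_zscore(plates)
    treated = df[df["role"] == "treated"]
    prof = (treated.groupby(["patient_id", "compound_id", "concentration_nM"],
                            as_index=False)[["sf", "zscore"]].mean())
    conc = list(config.concentrations_nM)

    def _auc(g: pd.DataFrame) -> float:
        by_conc = g.set_index("concentration_nM")["sf"]
        try:
            return dose_auc([by_conc.get(c, np.nan) for c in conc], conc)
        except ValidationError:
            return np.nan

    auc = (prof.groupby(["patient_id", "compound_id"])
           .apply(_auc, include_groups=False).rename("auc").reset_index())
    return prof.merge(auc, on=["patient_id", "compound_id"])


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture for the background model
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """A fitted two-Gaussian background/active model for one (patient, dose)."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    background_index: int
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    patient_id: str | None = None
    concentration_nM: float | None = None
    threshold: float | None = None
    degenerate: bool = False

    @property
    def background_mean(self) -> float:
        return self.means[self.background_index]

    @property
    def background_sd(self) -> float:
        return self.sds[self.background_index]


def _mixture_loglik(x, w, mu, sd):
    comp = np.stack([np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k])
                     for k in range(2)])
    return comp, float(logsumexp(comp, axis=0).sum())


def fit_background_mixture(values: Sequence[float],
                           seed: int = 0,
                           background_anchor: float = 1.0,
                           max_iter: int = 500,
                           tol: float = 1e-6) -> MixtureFit:
    """EM fit of a two-component univariate Gaussian mixture.

    Initialisation anchors the background component at ``background_anchor``
    (1.0 for SF readouts, 0.0 for z-scores) with weight 0.9 and the sample
    sd; the active component starts at the 5th percentile of the data with
    weight 0.1.  Convergence: log-likelihood improvement < ``tol`` or
    ``max_iter`` iterations.  A degenerate outcome (component sd < 1e-6 or
    weight < 1e-3) falls back to a single background Gaussian.

    The ``seed`` parameter is accepted for interface stability; the
    deterministic initialisation makes the fit seed-independent.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 20:
        raise ValidationError(f"mixture fit needs >= 20 values, got {x.size}")
    sample_sd = float(x.std(ddof=1))
    if sample_sd == 0:
        return _single_gaussian_fallback(x, background_anchor)

    w = np.array([0.9, 0.1])
    mu = np.array([background_anchor, float(np.percentile(x, 5))])
    sd = np.array([sample_sd, sample_sd])

    trace: list[float] = []
    comp, ll = _mixture_loglik(x, w, mu, sd)
    for _ in range(max_iter):
        # E-step
        with np.errstate(under="ignore"):
            log_resp = comp - logsumexp(comp, axis=0)
            resp = np.exp(log_resp)
        # M-step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-12):
            break
        w = nk / x.size
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
        sd = np.sqrt(np.maximum(var, 0.0))
        if np.any(sd < 1e-12):
            break
        comp, new_ll = _mixture_loglik(x, w, mu, sd)
        trace.append(new_ll)
        if new_ll - ll < tol and len(trace) > 1:
            ll = new_ll
            break
        ll = new_ll

    if np.any(sd < 1e-6) or np.any(w < 1e-3):
        logger.warning("degenerate mixture fit (sd=%s, w=%s); falling back to "
                       "single background Gaussian", sd, w)
        return _single_gaussian_fallback(x, background_anchor)

    bg = int(np.argmin(np.abs(mu - background_anchor)))
    return MixtureFit(weights=(float(w[0]), float(w[1])),
                      means=(float(mu[0]), float(mu[1])),
                      sds=(float(sd[0]), float(sd[1])),
                      background_index=bg, loglik=ll, loglik_trace=trace)


def _single_gaussian_fallback(x: np.ndarray, anchor: float) -> MixtureFit:
    m, s = float(x.mean()), float(x.std(ddof=1))
    ll = float(stats.norm.logpdf(x, m, max(s, 1e-12)).sum())
    return MixtureFit(weights=(1.0, 0.0), means=(m, m), sds=(s, s),
                      background_index=0, loglik=ll, loglik_trace=[ll],
                      degenerate=True)


def activity_threshold(fit: MixtureFit, hit_percentile: float = 0.01) -> float:
    """Lower quantile of the fitted background Gaussian.

    ``hit_percentile`` is on the percentile scale: 0.01 means the 0.01th
    percentile (tail probability 1e-4), so the default threshold is
    mu_bg - 3.719 * sd_bg.
    """
    if fit.background_sd == 0:
        warnings.warn("background sd is 0; threshold equals the background mean")
        return fit.background_mean
    z = stats.norm.ppf(hit_percentile / 100.0)
    return float(fit.background_mean + z * fit.background_sd)


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------

@dataclass
class HitCall:
    patient_id: str
    compound_id: str
    below_threshold: dict[float, bool]  # concentration -> strictly below?
    is_strong_hit: bool


def classify_strong_hits(profiles: pd.DataFrame,
                         thresholds: Mapping[tuple[str, float], float],
                         config: ScreenConfig | None = None,
                         ) -> list[HitCall]:
    """Strong hit = readout strictly below the threshold at EVERY dose.

    ``profiles`` is the long table from :func:`build_profiles`;
    ``thresholds`` maps (patient_id, concentration_nM) to the activity
    threshold.  Exact equality with a threshold is not "below".  The
    study-level hit set is the union over patients (use
    :func:`strong_hit_union`), each call retaining patient provenance.
    """
    config = config or ScreenConfig()
    col = "sf" if config.readout == "survival_fraction" else "zscore"
    conc = list(config.concentrations_nM)
    calls = []
    for (pat, comp), g in profiles.groupby(["patient_id", "compound_id"]):
        by_conc = g.set_index("concentration_nM")[col]
        flags = {}
        for c in conc:
            key = (pat, c)
            if key not in thresholds:
                raise ValidationError(f"missing threshold for {key}")
            v = by_conc.get(c, np.nan)
            flags[c] = bool(not math.isnan(v) and v < thresholds[key])
        calls.append(HitCall(patient_id=pat, compound_id=comp,
                             below_threshold=flags,
                             is_strong_hit=all(flags.values())))
    return calls


def strong_hit_union(calls: Sequence[HitCall]) -> set[str]:
    """Compounds that are a strong hit in at least one patient."""
    return {c.compound_id for c in calls if c.is_strong_hit}


@dataclass
class ScreenResult:
    profiles: pd.DataFrame
    fits: list[MixtureFit]
    thresholds: dict[tuple[str, float], float]
    calls: list[HitCall]

    @property
    def strong_hits(self) -> set[str]:
        return strong_hit_union(self.calls)


def analyze_screen(plates: ScreenPlateSet,
                   config: ScreenConfig | None = None,
                   seed: int = 0) -> ScreenResult:
    """Full screen analysis: readouts → per-(patient,dose) mixtures → hits.

    Mixtures are fitted on the pooled treated-compound readouts of each
    (patient, concentration), combining all subtypes/plates for that
    patient, per the configured readout.
    """
    config = config or ScreenConfig()
    profiles = build_profiles(plates, config)
    col = "sf" if config.readout == "survival_fraction" else "zscore"
    anchor = 1.0 if config.readout == "survival_fraction" else 0.0
    fits, thresholds = [], {}
    for (pat, conc), g in profiles.groupby(["patient_id", "concentration_nM"]):
        fit = fit_background_mixture(g[col].to_numpy(), seed=seed,
                                     background_anchor=anchor)
        fit.patient_id, fit.concentration_nM = pat, float(conc)
        fit.threshold = activity_threshold(fit, config.hit_percentile)
        fits.append(fit)
        thresholds[(pat, float(conc))] = fit.threshold
    calls = classify_strong_hits(profiles, thresholds, config)
    return ScreenResult(profiles=profiles, fits=fits,
                        thresholds=thresholds, calls=calls)
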