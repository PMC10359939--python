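"""Data-driven selection of the compound-similarity cutoff.

The scan asks: above which structural-similarity threshold do compound
pairs genuinely behave as redundant probes?  It rests on the assumption
that structurally similar compounds share similar activity distributions.
For each candidate threshold t on a grid, all subsampled compound pairs
with similarity >= t are collected and the two members' log10 activity
value sets are compared with the two-sample Kolmogorov-Smirnov statistic
D.  An AIC-style score summarises how well "called similar" agrees with
"same activity distribution":

    AIC(t) = m_t * ln(SS_t / m_t + eps) + 2,    SS_t = sum of D_ij^2

with eps = 1e-12 and one free parameter (the threshold itself).  Low mean
squared D among above-threshold pairs → low score.  The admissible
threshold (>= min_pairs evaluated pairs) minimising the score is selected
per seed (ties broken towards the largest t); the final cutoff is the
median over seeds.  The scoring function is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem_space import FingerprintSet, similarity
from .core_io import BioactivityTable, FilterConfig, ValidationError

_EPS = 1e-12


def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D = sup |F_x - F_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("ks_statistic requires non-empty samples")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


def aic_score(d_values: np.ndarray, k: int = 1) -> float:
    """Residual-style AIC over K-S distances: m*ln(SS/m + eps) + 2k."""
    m = len(d_values)
    ss = float(np.sum(np.square(d_values)))
    return m * np.log(ss / m + _EPS) + 2 * k


@dataclass
class ThresholdScanResult:
    """Grid scan outcome: per-seed score tables and the selected cutoff."""

    grid: np.ndarray
    per_seed: list[pd.DataFrame]  # columns: t, m, mean_D, aic, admissible
    selected_per_seed: list[float]
    selected: float
    seeds: list[int] = field(default_factory=list)

    @property
    def aggregate(self) -> pd.DataFrame:
        """Mean m/mean_D/aic over seeds, per grid threshold."""
        cat = pd.concat(self.per_seed)
        return cat.groupby("t", as_index=False).agg(
            m=("m", "mean"), mean_D=("mean_D", "mean"), aic=("aic", "mean"),
            admissible=("admissible", "all"))


def threshold_grid(config: FilterConfig) -> np.ndarray:
    step = config.grid_step
    n = int(round((config.grid_hi - config.grid_lo) / step))
    return np.round(config.grid_lo + step * np.arange(n + 1), 10)


def _median_on_grid(values: Sequence[float]) -> float:
    """Median that stays on the grid (lower-middle for even counts)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2] if len(s) % 2 == 0 else s[len(s) // 2]


def select_similarity_threshold(
        fps: FingerprintSet,
        activities: BioactivityTable,
        config: FilterConfig | None = None,
        seeds: Sequence[int] = (0, 1, 2),
        kind: str = "ECFP4",
        score_fn: Callable[[np.ndarray], float] = aic_score,
) -> ThresholdScanResult:
    """Scan the similarity grid and pick the cutoff minimising the score.

    Per seed, a uniform without-replacement subsample of
    ``config.subsample_fraction`` of the fingerprinted compounds is drawn;
    pairs where either member has fewer than 3 activity values are skipped
    (a K-S statistic on fewer points is degenerate).
    """
    config = config or FilterConfig()
    grid = threshold_grid(config)
    ids = sorted(cid for cid in fps.compound_ids if fps.has(cid, kind))
    # pooled log10 activity values per compound
    df = activities.df
    logv = np.log10(df["value_nM"].to_numpy(dtype=float))
    values: dict[str, np.ndarray] = {
        cid: logv[idx] for cid, idx in df.groupby("compound_id").indices.items()}
    if len(ids) < 20:
        raise ValidationError("need >= 20 fingerprinted compounds for the scan")

    per_seed, selected_per_seed = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        n_sub = max(2, int(round(config.subsample_fraction * len(ids))))
        sample = sorted(rng.choice(len(ids), size=n_sub, replace=False))
        sub = [ids[i] for i in sample]

        sims, dvals = [], []
        for i in range(len(sub)):
            fi = fps.get(sub[i], kind)
            vi = values.get(sub[i])
            for j in range(i + 1, len(sub)):
                s = similarity(fi, fps.get(sub[j], kind))
                if s < grid[0]:
                    continue  # never enters any threshold bucket
                vj = values.get(sub[j])
                if vi is None or vj is None or len(vi) < 3 or len(vj) < 3:
                    continue
                sims.append(s)
                dvals.append(ks_statistic(vi, vj))
        sims = np.asarray(sims)
        dvals = np.asarray(dvals)

        rows = []
        for t in grid:
            mask = sims >= t
            m = int(mask.sum())
            if m == 0:
                rows.append((t, 0, np.nan, np.nan, False))
                continue
            d = dvals[mask]
            rows.append((t, m, float(d.mean()), float(score_fn(d)),
                         m >= config.min_pairs))
        scan = pd.DataFrame(rows, columns=["t", "m", "mean_D", "aic", "admissible"])
        per_seed.append(scan)

        adm = scan[scan["admissible"]]
        if adm.empty:
            raise ValidationError(
                f"seed {seed}: no threshold had >= {config.min_pairs} evaluated "
                f"pairs; increase subsample_fraction or provide more compounds")
        best = adm["aic"].min()
        ties = adm[adm["aic"] <= best + 1e-9]
        selected_per_seed.append(float(ties["t"].max()))

    return ThresholdScanResult(
        grid=grid, per_seed=per_seed, selected_per_seed=selected_per_seed,
        selected=_median_on_grid(selected_per_seed), seeds=list(seeds))
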