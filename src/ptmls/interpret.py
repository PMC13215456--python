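"""Cross-modal interpretation of the fused risk model.

Feature contributions are measured by permutation importance on Harrell's
concordance index: permute one input column, re-encode through the trained
autoencoder, re-score risk, and record the drop in concordance with
survival. Cross-modal structure is summarized by a Spearman rank
correlation map over selected features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy import stats as sps

from .fusion import encode
from .prognosis import risk_score

__all__ = ["harrell_c", "permutation_importance", "spearman_map"]


def harrell_c(risk, times, events):
    """Harrell concordance: concordant / (concordant + discordant).

    Higher risk is expected to pair with shorter survival. Pairs tied on
    risk count one half; pairs uninformative under censoring are excluded.
    """
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() == 0:
        raise ValueError("no comparable pairs (zero events)")
    return float(concordance_index(times, -risk, events))


def permutation_importance(latent_model, risk_model, table, surv,
                           n_repeats=5, seed=0):
    """Mean concordance drop when each input feature is permuted.

    Returns a DataFrame (feature, modality, importance, rank) sorted by
    descending importance. A feature the encoder ignores has importance
    exactly 0 because permuting it leaves the latent code untouched.
    """
    if n_repeats < 3:
        raise ValueError("n_repeats must be >= 3")
    surv = surv.loc[table.index]
    t = surv["time"].to_numpy(float)
    e = surv["event"].to_numpy(int)
    base_risk = risk_score(risk_model, encode(latent_model, table))
    if np.ptp(base_risk.to_numpy()) == 0:
        raise ValueError("degenerate risk: constant across samples")
    baseline = harrell_c(base_risk, t, e)
    rng = np.random.default_rng(seed)
    rows = []
    for col in table.columns:
        drops = []
        for _ in range(n_repeats):
            perm = table.copy()
            perm[col] = rng.permutation(perm[col].to_numpy())
            r = risk_score(risk_model, encode(latent_model, perm))
            drops.append(baseline - harrell_c(r, t, e))
        modality = "expr" if str(col).startswith("expr_") else "path"
        rows.append({"feature": col, "modality": modality,
                     "importance": float(np.mean(drops)),
                     "n_repeats": n_repeats})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False,
                                         kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def spearman_map(table, features=None):
    """Spearman rank-correlation matrix (average ranks for ties)."""
    cols = list(features) if features is not None else list(table.columns)
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    X = table[cols].to_numpy(float)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        warnings.warn("constant column(s): correlation undefined, set to NaN")
    rho = sps.spearmanr(X).statistic if len(cols) > 2 else None
    if len(cols) == 1:
        rho = np.ones((1, 1))
    elif len(cols) == 2:
        rho = np.array([[1.0, sps.spearmanr(X[:, 0], X[:, 1]).statistic]] * 2)
        rho[1, 0] = rho[0, 1]
        np.fill_diagonal(rho, 1.0)
    rho = np.asarray(rho, float)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    return pd.DataFrame(rho, index=cols, columns=cols)
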