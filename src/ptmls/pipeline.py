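"""End-to-end multimodal survival pipeline.

Glues the stages together: assemble the expression + pathomics table,
split 7:3, train the autoencoder on the training partition, encode both
partitions, Cox-screen the latent dimensions, compute the risk score,
stratify at the training median and summarize the survival separation
(log-rank test and group hazard ratio) on both partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import fusion, prognosis

__all__ = ["PipelineResult", "run_multimodal", "cohort_tables"]


@dataclass
class PipelineResult:
    latent_model: object
    risk_model: object
    train_ids: object
    val_ids: object
    risk: pd.Series
    groups: pd.Series
    train_hr: float
    train_hr_ci: tuple
    train_logrank_p: float
    val_hr: float
    val_hr_ci: tuple
    val_logrank_p: float


def cohort_tables(cohort):
    """Synthetic-cohort arrays as (expr_df, path_df, surv_df)."""
    expr = pd.DataFrame(cohort.expr, index=cohort.sample_ids,
                        columns=[f"f{i}" for i in range(cohort.expr.shape[1])])
    path = pd.DataFrame(cohort.path, index=cohort.sample_ids,
                        columns=[f"f{i}" for i in range(cohort.path.shape[1])])
    surv = pd.DataFrame({"time": cohort.times, "event": cohort.events},
                        index=cohort.sample_ids)
    return expr, path, surv


def _summarize(groups, surv):
    high = surv[groups == "high"]
    low = surv[groups == "low"]
    chi2, p = prognosis.logrank(high, low)
    hr, ci, _ = prognosis.group_hr(groups, surv)
    return hr, ci, p


def run_multimodal(expr, path, surv, seed=0, ratio=0.7, alpha_screen=0.05,
                   ae_config=None, cluster=False):
    """Run assemble -> split -> autoencoder -> screen -> risk -> stratify."""
    table = fusion.assemble(expr, path)
    surv = surv.loc[table.index]
    train_ids, val_ids = fusion.split(table, ratio=ratio, seed=seed)
    cfg = ae_config or fusion.AEConfig(seed=seed)
    model = fusion.train_autoencoder(table.loc[train_ids], cfg)
    lat_train = fusion.encode(model, table.loc[train_ids])
    lat_val = fusion.encode(model, table.loc[val_ids])
    rm = prognosis.fit_risk_model(lat_train, surv.loc[train_ids],
                                  alpha_screen=alpha_screen, seed=seed,
                                  cluster=cluster)
    risk_train = prognosis.risk_score(rm, lat_train)
    risk_val = prognosis.risk_score(rm, lat_val)
    groups_train = prognosis.stratify(risk_train, rm.median_cutoff)
    groups_val = prognosis.stratify(risk_val, rm.median_cutoff)
    t_hr, t_ci, t_p = _summarize(groups_train, surv.loc[train_ids])
    v_hr, v_ci, v_p = _summarize(groups_val, surv.loc[val_ids])
    return PipelineResult(
        latent_model=model, risk_model=rm, train_ids=train_ids,
        val_ids=val_ids,
        risk=pd.concat([risk_train, risk_val]),
        groups=pd.concat([groups_train, groups_val]),
        train_hr=t_hr, train_hr_ci=t_ci, train_logrank_p=t_p,
        val_hr=v_hr, val_hr_ci=v_ci, val_logrank_p=v_p)
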