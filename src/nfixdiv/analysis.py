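"""Model battery over the change table, guild contrasts, and diagnostics.

This is the inferential layer of the resurvey analysis.  Each response
(change in N-fixer richness proportion, in N-fixer Faith's PD, and in the
N-fixer share of total PD; optionally MPD/MNTD) is regressed on the three
environmental predictors — cumulative N deposition, temperature change,
aridity change — plus the response's baseline value (which absorbs
regression to the mean), with a random intercept for study site.
Predictors are standardized to mean 0, SD 1 so slopes are comparable
across predictors; collinearity is screened with variance inflation
factors.  A signed cube-root response transform is available for the
heavy-tailed PD changes.

Guild comparisons fit per-plot guild PD (lost / gained / conserved) on
guild identity with a site random intercept, refitting under each
reference level so every pairwise contrast is read off directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .lmm import RandomInterceptLM, RandomInterceptLMResults

__all__ = [
    "standardize",
    "cube_root",
    "vif",
    "fit_change_model",
    "fit_all_models",
    "guild_pairwise",
    "influence_report",
    "RESPONSE_BASELINES",
]

# response column -> its baseline covariate in the change table
RESPONSE_BASELINES = {
    "delta_prop_rich": "baseline_prop_rich",
    "delta_pd": "baseline_pd",
    "delta_prop_pd": "baseline_prop_pd",
    "delta_mpd": "baseline_mpd",
    "delta_mntd": "baseline_mntd",
}

ENV_PREDICTORS = ["cum_n", "delta_t", "delta_ai"]


def standardize(table: pd.DataFrame, columns) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale `columns` to mean 0, sample SD 1.

    Returns the transformed copy and a frame of the (mean, sd) used, so
    coefficients can be mapped back to the original units.
    """
    out = table.copy()
    params = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (x - mu) / sd
        params[col] = {"mean": mu, "sd": sd}
    return out, pd.DataFrame(params).T.rename_axis("column")


def cube_root(x):
    """Signed cube root |x|^(1/3) * sign(x): monotone, odd, 0 -> 0."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.abs(x) ** (1.0 / 3.0)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j).

    R2_j comes from the OLS regression (with intercept) of predictor j on
    the other predictors.  Perfectly collinear columns report ``inf``
    with a warning rather than raising, matching screening practice.
    """
    if design.shape[1] < 2:
        raise ValueError("vif needs at least two predictors")
    X = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack(
            [np.ones(len(X)), np.delete(X, j, axis=1)]
        )
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {name!r} is perfectly collinear", stacklevel=2)
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def fit_change_model(
    table: pd.DataFrame,
    response: str,
    *,
    baseline: str | None = None,
    extra_predictors: tuple[str, ...] = (),
    transform: bool = False,
    df_rule: str = "containment",
    reml: bool = True,
) -> RandomInterceptLMResults:
    """Fit one response against the standard predictor set.

    Fixed effects: cumulative N, delta T, delta AI, the baseline value of
    the response, and any `extra_predictors` (e.g. canopy-cover change);
    all standardized.  Random intercept: site.  With ``transform=True``
    the response is signed-cube-root transformed first.
    """
    baseline = baseline or RESPONSE_BASELINES.get(response)
    predictors = [*ENV_PREDICTORS]
    if baseline is not None:
        predictors.append(baseline)
    predictors.extend(extra_predictors)
    work = table[["site", response, *predictors]].copy()
    work, _ = standardize(work, predictors)
    if transform:
        work[response] = cube_root(work[response])
    model = RandomInterceptLM.from_dataframe(
        work, response=response, predictors=predictors, group="site"
    )
    return model.fit(reml=reml, df_rule=df_rule)


def fit_all_models(
    table: pd.DataFrame,
    *,
    responses=("delta_prop_rich", "delta_pd", "delta_prop_pd"),
    include_distance_metrics: bool = False,
    transform: bool = False,
    include_canopy: bool = False,
    df_rule: str = "containment",
) -> dict[str, RandomInterceptLMResults]:
    """Fit the battery of change models on one change table.

    Returns a dict keyed by response name, with ``<response>_cuberoot``
    entries added when `transform` is requested.  Each response is fitted
    independently; requesting extra variants never alters the others.
    """
    responses = list(responses)
    if include_distance_metrics:
        responses += ["delta_mpd", "delta_mntd"]
    extra = ("delta_canopy",) if include_canopy else ()
    fits: dict[str, RandomInterceptLMResults] = {}
    for resp in responses:
        if resp not in table.columns:
            raise KeyError(f"response {resp!r} not in change table")
        fits[resp] = fit_change_model(
            table, resp, extra_predictors=extra, df_rule=df_rule
        )
        if transform:
            fits[resp + "_cuberoot"] = fit_change_model(
                table, resp, extra_predictors=extra, transform=True,
                df_rule=df_rule,
            )
    return fits


def results_table(fits: dict[str, RandomInterceptLMResults]) -> pd.DataFrame:
    """Long coefficient table over a battery of fits."""
    frames = []
    for name, res in fits.items():
        f = res.to_frame().reset_index()
        f.insert(0, "response", name)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def guild_pairwise(
    guild_table: pd.DataFrame,
    *,
    metric: str = "faith_pd",
    df_rule: str = "containment",
) -> pd.DataFrame:
    """All pairwise guild contrasts of a diversity metric.

    Fits ``metric ~ guild`` with a site random intercept once per
    reference level, reading each contrast "A - B" off the coefficient of
    guild A in the model with B as reference.  Returns one row per
    unordered pair: comparison, value, SE, t, df, p.  Guilds absent from
    the data drop out with a warning.
    """
    levels = [g for g in ("conserved", "lost", "gained")
              if g in set(guild_table["guild"])]
    if len(levels) < 2:
        raise ValueError("need at least two guild levels for contrasts")
    dropped = {"conserved", "lost", "gained"} - set(levels)
    if dropped:
        warnings.warn(
            f"guilds absent from data, contrasts omitted: {sorted(dropped)}",
            stacklevel=2,
        )
    wanted = [
        ("conserved", "lost"),
        ("conserved", "gained"),
        ("gained", "lost"),
    ]
    rows = []
    for a, b in wanted:
        if a not in levels or b not in levels:
            continue
        # model with b as reference: dummies for the other levels
        others = [g for g in levels if g != b]
        work = guild_table[["site", "guild", metric]].copy()
        for g in others:
            work[f"guild_{g}"] = (work["guild"] == g).astype(float)
        model = RandomInterceptLM.from_dataframe(
            work, response=metric,
            predictors=[f"guild_{g}" for g in others], group="site",
        )
        res = model.fit(df_rule=df_rule)
        term = f"guild_{a}"
        rows.append(
            {
                "comparison": f"{a} - {b}",
                "value": res.params[term],
                "se": res.bse[term],
                "t": res.tvalues[term],
                "df": res.df_t,
                "p": res.pvalues[term],
            }
        )
    return pd.DataFrame(rows)


def influence_report(
    res: RandomInterceptLMResults, *, resid_threshold: float = 4.0
) -> dict:
    """Outlier and influence screening; reports, never drops data.

    Flags observations with |standardized conditional residual| above
    `resid_threshold` and recomputes each fixed effect with one site left
    out at a time, reporting the largest absolute coefficient change.
    """
    m = res.model
    std_resid = res.resid() / res.resid_sd
    flagged = np.flatnonzero(np.abs(std_resid) > resid_threshold)
    loo = {}
    for g, label in enumerate(m.group_labels):
        keep = m._group_idx != g
        if keep.sum() <= m.exog.shape[1] + 2 or len(np.unique(m._group_idx[keep])) < 2:
            continue
        try:
            sub = RandomInterceptLM(
                m.endog[keep], m.exog[keep], m._group_idx[keep],
                exog_names=m.exog_names,
            ).fit(reml=res.reml)
        except (ValueError, RuntimeError):
            continue  # too few rows/groups left to refit; skip this site
        loo[label] = (sub.params - res.params).abs().max()
    loo = pd.Series(loo, name="max_abs_coef_change")
    return {
        "n_flagged_residuals": int(len(flagged)),
        "flagged_indices": flagged.tolist(),
        "max_std_resid": float(np.abs(std_resid).max()),
        "leave_one_site_out": loo,
        "most_influential_site": (loo.idxmax() if len(loo) else None),
    }
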