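"""High-level reporting: full diagnosis, deletion-impact tables, plots."""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .glm import ModelData, PoissonRegression, condition_index
from .influence import InfluenceTable, influence_table, one_step_delete, one_step_delete_liu
from .liu import LiuPoissonRegression

__all__ = ["DeletionImpactReport", "diagnose", "deletion_impact", "index_plot"]


def diagnose(
    data: ModelData,
    estimator: str = "ML",
    d_rule: str = "d1",
    d_value: float | None = None,
    cutoff_overrides: dict[str, float] | None = None,
    dffits_form: str = "jackknife",
) -> InfluenceTable:
    """Fit the requested estimator and return its full influence table.

    ``estimator`` is ``"ML"`` or ``"Liu"``; for Liu, ``d_rule`` chooses
    the shrinkage-parameter rule ('d1', 'd2' or 'fixed' with ``d_value``).
    """
    ml = PoissonRegression(fit_intercept=data.add_intercept).fit(data.X, data.y)
    if estimator.upper() == "ML":
        model = ml
    elif estimator.lower() == "liu":
        d = d_value if d_rule == "fixed" else d_rule
        if d is None:
            raise ValueError("d_rule='fixed' requires d_value")
        model = LiuPoissonRegression(d=d, fit_intercept=data.add_intercept).fit(
            data.X, data.y, base=ml
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    table = influence_table(
        model, data.X, data.y, cutoff_overrides=cutoff_overrides, dffits_form=dffits_form
    )
    table.metadata["condition_index"] = condition_index(data.X, "correlation")
    table.metadata["names"] = list(data.names)
    return table


@dataclass
class DeletionImpactReport:
    """Absolute percentage change in coefficients after deleting rows.

    ``changes`` has one row per coefficient (intercept first) and one
    column per deleted set, holding ``100 |beta_full - beta_del| /
    |beta_full|``.
    """

    estimator: str
    deleted_sets: list[list[int]]
    changes: pd.DataFrame
    refit_mode: str
    d_policy: str
    beta_full: np.ndarray


def _refit_beta(data: ModelData, keep: np.ndarray, estimator: str, d_rule, d_policy, d_full):
    ml = PoissonRegression(fit_intercept=data.add_intercept).fit(data.X[keep], data.y[keep])
    if estimator.upper() == "ML":
        return ml.beta_
    d = d_full if d_policy == "hold_d" else d_rule
    liu = LiuPoissonRegression(d=d, fit_intercept=data.add_intercept).fit(
        data.X[keep], data.y[keep], base=ml
    )
    return liu.beta_


def deletion_impact(
    data: ModelData,
    sets: list[list[int]],
    estimator: str = "ML",
    refit_mode: str = "exact_refit",
    d_policy: str = "refit_d",
    d_rule: str = "d1",
) -> DeletionImpactReport:
    """Coefficient changes from deleting observation sets (1-based).

    ``refit_mode="exact_refit"`` refits from scratch on the reduced data;
    ``"one_step"`` uses the closed-form single-deletion displacement and
    therefore only accepts singleton sets.  For the Liu estimator,
    ``d_policy`` controls whether the shrinkage parameter is re-selected
    on the reduced data (``"refit_d"``) or held at its full-data value
    (``"hold_d"``).
    """
    if not sets:
        raise ValueError("sets must be nonempty")
    n, p = data.n, data.p
    ml_full = PoissonRegression(fit_intercept=data.add_intercept).fit(data.X, data.y)
    if estimator.upper() == "ML":
        model_full = ml_full
    else:
        model_full = LiuPoissonRegression(d=d_rule, fit_intercept=data.add_intercept).fit(
            data.X, data.y, base=ml_full
        )
    beta_full = model_full.beta_
    near_zero = np.abs(beta_full) < 1e-6
    if near_zero.any():
        warn(
            "near-zero full-data coefficients make percentage changes unstable",
            RuntimeWarning,
            stacklevel=2,
        )

    cols = {}
    for s in sets:
        s = sorted(int(i) for i in s)
        if not s or min(s) < 1 or max(s) > n:
            raise ValueError(f"invalid observation set {s}")
        if n - len(s) <= p + 1:
            raise ValueError(f"deleting {s} leaves too few observations")
        label = ",".join(str(i) for i in s)
        if refit_mode == "exact_refit":
            keep = np.setdiff1d(np.arange(n), np.array(s) - 1)
            beta_del = _refit_beta(
                data, keep, estimator, d_rule, d_policy,
                getattr(model_full, "d_", None),
            )
            delta = beta_full - beta_del
        elif refit_mode == "one_step":
            if len(s) != 1:
                raise ValueError("one_step mode supports single deletions only")
            i = s[0] - 1
            if estimator.upper() == "ML":
                delta = one_step_delete(model_full, data.X, data.y, i)
            else:
                delta = one_step_delete_liu(model_full, data.X, data.y, i)
        else:
            raise ValueError(f"unknown refit_mode {refit_mode!r}")
        cols[label] = 100.0 * np.abs(delta) / np.abs(beta_full)

    names = ["intercept"] + list(data.names) if data.add_intercept else list(data.names)
    changes = pd.DataFrame(cols, index=names)
    return DeletionImpactReport(
        estimator=estimator.upper() if estimator.upper() == "ML" else "Liu",
        deleted_sets=[sorted(int(i) for i in s) for s in sets],
        changes=changes,
        refit_mode=refit_mode,
        d_policy=d_policy,
        beta_full=beta_full,
    )


def index_plot(table: InfluenceTable, measure: str, out_path) -> None:
    """Stem plot of one influence measure with its cutoff rule.

    Flagged observations are drawn as filled red markers; the measure's
    cutoff is a dashed horizontal line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if measure not in table.cutoffs:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(table.cutoffs)}")
    obs = table.frame["obs"].to_numpy()
    vals = table.frame[measure].to_numpy(dtype=float)
    if measure == "dffits":
        vals = np.abs(vals)
    flagged = table.flags[measure]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.vlines(obs, 0, vals, color="grey", lw=1)
    ax.plot(obs[~flagged], vals[~flagged], "o", color="steelblue", ms=4, label="observation")
    if flagged.any():
        ax.plot(obs[flagged], vals[flagged], "o", color="crimson", ms=6, label="flagged")
    ax.axhline(table.cutoffs[measure], ls="--", color="black", lw=1, label="cutoff")
    ax.set_xlabel("observation")
    ax.set_ylabel(measure if measure != "dffits" else "|dffits|")
    ax.set_title(f"{measure} ({table.estimator})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
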