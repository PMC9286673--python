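"""Growth-curve analysis of chain metrics with linear mixed-effects models.

Each dependent variable is modeled over generations with sum-coded
condition (+1/-1), centered orthonormal polynomial generation terms
(linear + quadratic), their interactions, and by-chain random intercepts
and generation slopes — for item-level variables (signal length) also a
size contrast and meaning-level variance components.  Fits use REML via
statsmodels MixedLM; p-values are Wald tests against a normal reference.
On convergence failure the random structure is simplified stepwise
(quadratic slope, then linear slope, then meaning components), and the
level reached is recorded with the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core import Chain
from .transmission import experiment_metrics, signal_length_table

Z_THRESHOLD = 1.96


def orthogonal_poly(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Centered orthonormal polynomial basis over the observed values.

    Columns are mutually orthogonal, orthogonal to the intercept, and unit
    norm over the data vector (the convention of R's ``poly``).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("orthogonal polynomial basis needs a non-constant grid")
    X = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, R = np.linalg.qr(X)
    basis = Q[:, 1:] * np.sign(np.diag(R))[1:]
    return basis


def sum_code(labels: pd.Series) -> tuple[pd.Series, dict[str, int]]:
    """Sum-code a two-level factor as +1/-1 (alphabetically first level = +1).

    For the size factor this puts ``large`` at +1, so an iconic
    longer-signals-for-larger-referents effect has a positive coefficient.
    """
    levels = sorted(labels.unique())
    if len(levels) > 2:
        raise ValueError(f"sum coding requires <= 2 levels, got {levels}")
    coding = {levels[0]: 1} if len(levels) == 1 else {levels[0]: 1, levels[1]: -1}
    # 'large' < 'small' and 'long' < 'short' alphabetically, so large=+1
    return labels.map(coding).astype(float), coding


@dataclass
class ModelSpec:
    """Fixed/random structure of one growth-curve model."""

    dv: str
    item_level: bool = False
    include_size: bool = False  # size * condition * generation (iconicity model)
    max_simplification: int = 3


@dataclass
class ModelFit:
    """A fitted growth-curve model: tidy fixed-effect table plus fit metadata."""

    estimates: pd.DataFrame  # term, estimate, se, z, p
    converged: bool
    simplification_level: int
    formula: str
    re_formula: str
    vc_formula: dict | None
    coding: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.estimates.set_index("term").loc[term, "estimate"])


def build_model_frame(
    chains: "list[Chain] | pd.DataFrame",
    dv: str,
    item_level: bool = False,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Assemble the modeling frame for one dependent variable.

    Accepts either chains (metrics are computed first) or a precomputed
    metrics table from :func:`~signalchains.transmission.experiment_metrics`
    / :func:`~signalchains.transmission.signal_length_table`.  The frame
    carries the DV as ``value``, orthonormal generation polynomials ``g1``
    and ``g2``, the sum-coded condition ``cond`` (and ``size_c`` at item
    level), and grouping ids; rows with missing DV (e.g. generation 0 for
    parent-relative metrics) are dropped.
    """
    if isinstance(chains, pd.DataFrame):
        metrics = chains
    elif item_level and dv == "signal_length":
        metrics = signal_length_table(chains)
    else:
        metrics = experiment_metrics(chains, n_perm=n_perm, seed=seed)
    if dv not in metrics.columns:
        raise ValueError(f"dependent variable {dv!r} not in metrics table")

    frame = metrics.loc[metrics[dv].notna(), :].copy()
    if not np.isfinite(frame[dv].astype(float)).all():
        bad = frame.index[~np.isfinite(frame[dv].astype(float))].tolist()
        raise ValueError(f"non-finite values of {dv!r} at rows {bad}")
    frame["value"] = frame[dv].astype(float)
    basis = orthogonal_poly(frame["generation"].to_numpy(), degree=2)
    frame["g1"], frame["g2"] = basis[:, 0], basis[:, 1]
    frame["cond"], cond_coding = sum_code(frame["condition"])
    frame.attrs["condition_coding"] = cond_coding
    frame.attrs["condition_constant"] = frame["cond"].nunique() == 1
    if item_level:
        frame["size_c"], size_coding = sum_code(frame["size"])
        frame.attrs["size_coding"] = size_coding
    return frame.reset_index(drop=True)


def _random_structure(spec: ModelSpec, level: int) -> tuple[str, dict | None]:
    """Simplification ladder: full by-chain slopes -> drop quadratic ->
    linear slope only -> intercept only; meaning variance components (item
    level) are dropped at the last step."""
    re_ladder = ["~ 1 + g1 + g2", "~ 1 + g1", "~ 1", "~ 1"]
    re_formula = re_ladder[min(level, 3)]
    vc = None
    if spec.item_level and level < 3:
        vc = {"meaning": "0 + C(meaning_id)"}
    return re_formula, vc


def fit_growth_model(frame: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML mixed-effects fit with stepwise random-structure simplification.

    Meaning-level random effects (crossed with chain in the design) are
    approximated as variance components nested within chain.
    """
    if frame.attrs.get("condition_constant", False) and "cond" in _fixed_formula(spec):
        warnings.warn("single condition: the condition contrast is constant")
    formula = _fixed_formula(spec)
    if float(np.ptp(frame["value"])) == 0.0:
        # degenerate outcome: zero variance, closed-form fit (mixed REML is undefined)
        terms = _term_names(spec)
        est = pd.DataFrame(
            {
                "term": terms,
                "estimate": [float(frame["value"].iloc[0])] + [0.0] * (len(terms) - 1),
                "se": 0.0,
                "z": np.nan,
                "p": np.nan,
            }
        )
        return ModelFit(
            estimates=est,
            converged=True,
            simplification_level=0,
            formula=formula,
            re_formula="(degenerate)",
            vc_formula=None,
            coding={
                "condition": frame.attrs.get("condition_coding", {}),
                "size": frame.attrs.get("size_coding", {}),
            },
        )
    last_exc: Exception | None = None
    for level in range(spec.max_simplification + 1):
        re_formula, vc_formula = _random_structure(spec, level)
        ok = False
        res = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    model = smf.mixedlm(
                        formula,
                        data=frame,
                        groups=frame["chain_id"],
                        re_formula=re_formula,
                        vc_formula=vc_formula,
                    )
                    res = model.fit(reml=True, method=method, maxiter=200)
                k = model.k_fe
                ok = bool(res.converged) and np.all(np.isfinite(res.bse.iloc[:k]))
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                ok = False
                res = None
            if ok:
                break
        if ok:
            names = res.model.exog_names
            est = pd.DataFrame(
                {
                    "term": names,
                    "estimate": res.params.iloc[: len(names)].to_numpy(),
                    "se": res.bse.iloc[: len(names)].to_numpy(),
                    "z": res.tvalues.iloc[: len(names)].to_numpy(),
                    "p": res.pvalues.iloc[: len(names)].to_numpy(),
                }
            )
            return ModelFit(
                estimates=est,
                converged=True,
                simplification_level=level,
                formula=formula,
                re_formula=re_formula,
                vc_formula=vc_formula,
                coding={
                    "condition": frame.attrs.get("condition_coding", {}),
                    "size": frame.attrs.get("size_coding", {}),
                },
            )
    raise RuntimeError(
        f"growth model failed to converge at every simplification level: {last_exc}"
    )


def _term_names(spec: ModelSpec) -> list[str]:
    if spec.include_size:
        return [
            "Intercept", "size_c", "cond", "size_c:cond", "g1", "g2",
            "size_c:g1", "size_c:g2", "cond:g1", "cond:g2",
            "size_c:cond:g1", "size_c:cond:g2",
        ]
    return ["Intercept", "cond", "g1", "g2", "cond:g1", "cond:g2"]


def _fixed_formula(spec: ModelSpec) -> str:
    if spec.include_size:
        return "value ~ size_c * cond * (g1 + g2)"
    return "value ~ cond * (g1 + g2)"


@dataclass
class SignificanceSummary:
    """Mantel-z exceedance summary: where does z clear the threshold?"""

    mean_z: pd.DataFrame  # condition, generation, mean_z
    per_condition: pd.DataFrame  # condition, frac_cells_above, any_mean_above
    threshold: float


def significance_summary(
    metrics: pd.DataFrame, threshold: float = Z_THRESHOLD
) -> SignificanceSummary:
    """Summarize per-generation mean Mantel z against a threshold.

    Reports, per condition, the generation-wise mean z, the fraction of
    (chain, generation) cells whose individual z exceeds the threshold,
    and whether any per-generation mean does.
    """
    z = metrics.loc[metrics["mantel_z"].notna(), ["condition", "generation", "mantel_z"]]
    mean_z = (
        z.groupby(["condition", "generation"], as_index=False)["mantel_z"]
        .mean()
        .rename(columns={"mantel_z": "mean_z"})
    )
    rows = []
    for cond, cdf in z.groupby("condition"):
        means = mean_z.loc[mean_z["condition"] == cond, "mean_z"]
        rows.append(
            {
                "condition": cond,
                "frac_cells_above": float((cdf["mantel_z"] > threshold).mean()),
                "any_mean_above": bool((means > threshold).any()),
            }
        )
    return SignificanceSummary(
        mean_z=mean_z, per_condition=pd.DataFrame(rows), threshold=threshold
    )
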