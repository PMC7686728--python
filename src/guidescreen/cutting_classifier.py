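"""Classify guide cutting behaviour from control fold-change phenotypes.

A 4-component univariate Gaussian mixture is fitted by EM to the pooled fold
changes of targeting and non-targeting control guides. Component roles follow
the ordering of the fitted means: the highest mean captures the non-targeting
controls (no DNA cut, no phenotype), the next the targeting controls (cut but
neutral locus), and the two lowest means capture moderate and severe toxic
viability phenotypes. Library guides are then mapped to the control with the
most similar fold change and inherit that control's posterior component
membership: summed toxic-component posterior >= 80% means a target-dependent
viability phenotype, a confident targeting-like control means the guide likely
cut, a confident non-targeting-like control means it likely did not, anything
else is undetermined. Guides of core-essential reference genes are excluded
up front (their depletion is expected and uninformative about cutting).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from guidescreen.screen_data import FoldChangeTable


class GuideClass(str, enum.Enum):
    target_phenotype = "target_phenotype"
    likely_cutting = "likely_cutting"
    likely_not_cutting = "likely_not_cutting"
    undetermined = "undetermined"
    excluded_core_essential = "excluded_core_essential"


#: role labels keyed by component number (1-4, assigned by descending mean)
ROLES = {
    1: "nontargeting_like",
    2: "targeting_like",
    3: "toxic_moderate",
    4: "toxic_severe",
}


@dataclass
class MixtureFit:
    """Fitted 4-component univariate Gaussian mixture over control fold changes.

    Components are stored in role order 1..4 (descending mean): index 0 is the
    non-targeting-like component, index 3 the severe-toxicity component.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik_trace: list[float]
    converged: bool
    var_floor: float = 1e-4

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.sds**2 < self.var_floor - 1e-12).any():
            raise ValueError("component variance below floor")
        if not all(
            self.means[i] >= self.means[i + 1] for i in range(len(self.means) - 1)
        ):
            raise ValueError("components must be ordered by descending mean")

    @property
    def roles(self) -> dict[int, str]:
        return dict(ROLES)

    def responsibilities(self, values: np.ndarray) -> np.ndarray:
        """Posterior component membership, rows summing to 1; columns follow
        role order (component 1 first)."""
        values = np.asarray(values, dtype=float)
        dens = np.stack(
            [
                w * norm.pdf(values, loc=m, scale=s)
                for w, m, s in zip(self.weights, self.means, self.sds)
            ],
            axis=1,
        )
        dens = np.maximum(dens, 1e-300)
        return dens / dens.sum(axis=1, keepdims=True)


def fit_control_mixture(
    control_fcs: np.ndarray,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    var_floor: float = 1e-4,
    n_components: int = 4,
) -> MixtureFit:
    """EM fit of the control-phenotype mixture.

    Means are initialized at evenly spread data quantiles with a small seeded
    jitter; variances start at the data variance and are floored at
    ``var_floor`` throughout, so degenerate (constant) inputs converge with
    all means equal rather than collapsing. The log-likelihood is
    non-decreasing across iterations; non-convergence within ``max_iter``
    yields a warning and ``converged=False`` but still returns the fit.
    """
    x = np.asarray(control_fcs, dtype=float)
    if len(x) < max(n_components, 40):
        raise ValueError(
            f"need at least {max(n_components, 40)} control values, got {len(x)}"
        )
    rng = np.random.default_rng(seed)
    qs = (np.arange(n_components) + 0.5) / n_components
    means = np.quantile(x, qs)
    spread = max(float(x.std()), np.sqrt(var_floor))
    means = means + rng.normal(0, 1e-3 * spread, size=n_components)
    variances = np.full(n_components, max(float(x.var()), var_floor))
    weights = np.full(n_components, 1.0 / n_components)

    loglik_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        dens = np.stack(
            [
                w * norm.pdf(x, loc=m, scale=np.sqrt(v))
                for w, m, v in zip(weights, means, variances)
            ],
            axis=1,
        )
        total = np.maximum(dens.sum(axis=1), 1e-300)
        loglik = float(np.log(total).sum())
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / np.maximum(
            nk, 1e-300
        )
        variances = np.maximum(variances, var_floor)
        if loglik_trace and abs(loglik - loglik_trace[-1]) < tol:
            loglik_trace.append(loglik)
            converged = True
            break
        loglik_trace.append(loglik)
    if not converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning)

    order = np.argsort(-means, kind="stable")  # component 1 = highest mean
    return MixtureFit(
        weights=weights[order],
        means=means[order],
        sds=np.sqrt(variances[order]),
        loglik_trace=loglik_trace,
        converged=converged,
        var_floor=var_floor,
    )


def classify_guides(
    fc: FoldChangeTable,
    fit: MixtureFit,
    control_fcs: np.ndarray,
    core_essential: set[str],
    threshold: float = 0.80,
) -> pd.DataFrame:
    """Nearest-control classification of every guide in a fold-change table.

    Returns a frame indexed by guide with columns ``gene``, ``class``,
    ``nearest_control`` (index into ``control_fcs``) and posteriors
    ``p1``-``p4`` of the matched control.
    """
    controls = np.asarray(control_fcs, dtype=float)
    if len(controls) == 0:
        raise ValueError("no control fold changes given")
    order = np.lexsort((controls,))  # ties between controls -> lower fc wins
    sorted_controls = controls[order]
    resp = fit.responsibilities(sorted_controls)

    rows = []
    for g in fc.guide_ids:
        val = float(fc.fc.loc[g])
        gene = fc.gene_of.get(g, "")
        if gene in core_essential:
            rows.append((g, gene, GuideClass.excluded_core_essential.value, -1,
                         np.nan, np.nan, np.nan, np.nan))
            continue
        dists = np.abs(sorted_controls - val)
        # ties on distance: lower-fc control (earlier in the sorted order)
        idx = int(np.argmin(dists))
        p1, p2, p3, p4 = resp[idx]
        if p3 + p4 >= threshold:
            cls = GuideClass.target_phenotype
        elif p2 >= threshold:
            cls = GuideClass.likely_cutting
        elif p1 >= threshold:
            cls = GuideClass.likely_not_cutting
        else:
            cls = GuideClass.undetermined
        rows.append((g, gene, cls.value, int(order[idx]), p1, p2, p3, p4))
    return pd.DataFrame(
        rows,
        columns=["sgRNA", "gene", "class", "nearest_control", "p1", "p2", "p3", "p4"],
    ).set_index("sgRNA")


def class_by_provenance(
    classes: pd.DataFrame,
    provenance_of: dict[str, str],
    essential_calls: set[str],
) -> pd.DataFrame:
    """Contingency counts of guide class by provenance category, split by
    whether the target gene was called essential."""
    rows = []
    for g, row in classes.iterrows():
        rows.append(
            (
                provenance_of.get(g, "unknown"),
                row["gene"] in essential_calls,
                row["class"],
            )
        )
    df = pd.DataFrame(rows, columns=["category", "gene_essential", "class"])
    if df.empty:
        return pd.DataFrame(
            columns=["category", "gene_essential", "class", "count"]
        )
    out = (
        df.groupby(["category", "gene_essential", "class"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out
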