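"""Group comparisons and the pairwise significance matrix (PSM).

Two groups are compared by an unpaired two-sided t-test (Welch by
default); three or more by one-way ANOVA followed by all-pairs tests
feeding a PSM: one cell per unordered pair, green when p < alpha, red
otherwise, with the strict inequality so p exactly at alpha is not
significant.  The default all-pairs procedure is uncorrected pairwise
Welch t-tests; Holm-adjusted and Tukey HSD modes are available.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "PSMatrix", "compare_groups", "build_psm", "render_psm"]


@dataclass
class ComparisonResult:
    groups: list[str]
    omnibus_test: str  # "t" | "anova"
    omnibus_p: float
    pairwise: dict[tuple[str, str], float]
    method: str


@dataclass
class PSMatrix:
    """Pairwise significance matrix: one box per unordered group pair."""

    groups: list[str]
    comparisons: dict[frozenset, tuple[float, bool]]
    alpha: float = 0.05
    order: list[tuple[str, str]] = field(default_factory=list)

    def lookup(self, a: str, b: str) -> tuple[float, bool]:
        """Symmetric pair lookup: (p_value, significant)."""
        if a == b:
            raise KeyError("diagonal (self-comparison) is undefined")
        key = frozenset((a, b))
        if key not in self.comparisons:
            raise KeyError(f"no comparison for pair ({a!r}, {b!r})")
        return self.comparisons[key]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return self.order

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "alpha": self.alpha,
            "comparisons": [
                {
                    "group_a": a,
                    "group_b": b,
                    "p_value": self.lookup(a, b)[0],
                    "significant": self.lookup(a, b)[1],
                    "color": "green" if self.lookup(a, b)[1] else "red",
                }
                for a, b in self.order
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare_groups(
    samples: dict[str, np.ndarray],
    correction: str = "none",
    equal_var: bool = False,
) -> ComparisonResult:
    """Compare named groups of measurements.

    Two groups: unpaired two-sided t-test (Welch unless ``equal_var``).
    More: one-way ANOVA plus all-pairs tests — ``correction`` selects
    ``"none"`` (pairwise Welch/pooled t-tests at the nominal level),
    ``"holm"`` (Holm-adjusted pairwise p-values) or ``"tukey"`` (Tukey
    HSD, pooled variance by construction).
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in samples.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    if all(v.std(ddof=0) == 0 for v in arrays.values()):
        raise ValueError("zero within-group variance in every group")

    def _t(a, b):
        return float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)

    pairs = list(itertools.combinations(names, 2))
    if len(names) == 2:
        p = _t(arrays[names[0]], arrays[names[1]])
        return ComparisonResult(names, "t", p, {pairs[0]: p}, "welch" if not equal_var else "pooled")

    omnibus_p = float(sps.f_oneway(*arrays.values()).pvalue)
    if correction == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate([arrays[n] for n in names])
        labels = np.concatenate([[n] * len(arrays[n]) for n in names])
        res = pairwise_tukeyhsd(values, labels, alpha=0.05)
        pairwise = {
            (str(a), str(b)): float(p)
            for (a, b), p in zip(
                itertools.combinations(res.groupsunique, 2), res.pvalues
            )
        }
        method = "tukey"
    else:
        raw = {pair: _t(arrays[pair[0]], arrays[pair[1]]) for pair in pairs}
        if correction == "holm":
            from statsmodels.stats.multitest import multipletests

            adj = multipletests(list(raw.values()), method="holm")[1]
            pairwise = {pair: float(p) for pair, p in zip(raw, adj)}
            method = "welch+holm"
        elif correction == "none":
            pairwise = raw
            method = "welch" if not equal_var else "pooled"
        else:
            raise ValueError(f"unknown correction {correction!r}")
    return ComparisonResult(names, "anova", omnibus_p, pairwise, method)


def build_psm(
    result: ComparisonResult,
    alpha: float = 0.05,
    order: list[tuple[str, str]] | None = None,
) -> PSMatrix:
    """Assemble the PSM from pairwise p-values (green iff p < alpha)."""
    expected = list(itertools.combinations(result.groups, 2))
    order = order or sorted(expected)
    comparisons = {}
    lut = {frozenset(k): v for k, v in result.pairwise.items()}
    for a, b in order:
        key = frozenset((a, b))
        if key not in lut:
            raise ValueError(f"missing comparison for pair ({a!r}, {b!r})")
        p = lut[key]
        comparisons[key] = (p, bool(p < alpha))
    return PSMatrix(list(result.groups), comparisons, alpha, list(order))


def render_psm(psm: PSMatrix, path) -> None:
    """Render the PSM as a green/red box grid (SVG or any matplotlib format)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(psm.pairs)
    fig, ax = plt.subplots(figsize=(max(2, n * 0.8), 1.6))
    for i, (a, b) in enumerate(psm.pairs):
        _, sig = psm.lookup(a, b)
        ax.add_patch(
            plt.Rectangle((i, 0), 0.9, 0.9, color="green" if sig else "red")
        )
        ax.text(i + 0.45, -0.25, f"{a}\nvs\n{b}", ha="center", va="top", fontsize=6)
    ax.set_xlim(-0.1, n)
    ax.set_ylim(-1.6, 1.0)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
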