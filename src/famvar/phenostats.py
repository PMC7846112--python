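"""Group summaries and exact Mann–Whitney tests for plasma parameters.

With 3 cases and 7 controls, asymptotic rank tests are unreliable; the
two-sample comparison here enumerates all C(n1+n2, n1) assignments of the
pooled observations whenever that is feasible, giving an exact, tie-correct
null distribution of the U statistic.  Summaries report mean, sample SD
(n-1 denominator) and SEM = SD/sqrt(n), the convention used for the
published family plasma values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_ENUMERATION_LIMIT = 1_000_000


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float | None
    sem: float | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class MannWhitneyResult:
    U: float
    p_two_sided: float
    method: str  # exact_enumeration | normal_approx

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class GroupComparison:
    parameter: str
    units: str
    case: GroupSummary
    control: GroupSummary
    U: float | None
    p_two_sided: float | None
    method: str  # exact_enumeration | normal_approx | untestable

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "units": self.units,
            "case": self.case.to_dict(),
            "control": self.control.to_dict(),
            "U": self.U,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
        }


def summarize_group(values) -> GroupSummary:
    """Mean, sample SD and SEM of one group; SD/SEM are None when n = 1."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("group must contain at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("group values must be finite")
    mean = float(x.mean())
    if x.size == 1:
        return GroupSummary(1, mean, None, None)
    sd = float(x.std(ddof=1))
    return GroupSummary(int(x.size), mean, sd, sd / math.sqrt(x.size))


def mann_whitney_exact(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test, exact by enumeration where feasible.

    U is computed from mid-rank sums of the first group.  When
    C(n1+n2, n1) <= 10^6 the p-value is the exact probability, over all
    equally likely assignments of the pooled observed values into groups of
    the observed sizes, of a statistic at least as far from the null mean
    n1*n2/2 as observed (tie-correct by construction, since ties are
    enumerated as they stand).  Larger problems fall back to the normal
    approximation with tie-corrected variance and continuity correction;
    ``method`` flags which route was taken.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = int(x.size), int(y.size)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if math.comb(n, n1) <= EXACT_ENUMERATION_LIMIT:
        rank_list = ranks.tolist()
        offset = n1 * (n1 + 1) / 2.0
        threshold = abs(u_obs - mu) - 1e-9
        extreme = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            u = sum(rank_list[i] for i in combo) - offset
            if abs(u - mu) >= threshold:
                extreme += 1
            total += 1
        return MannWhitneyResult(u_obs, min(extreme / total, 1.0), "exact_enumeration")

    # tie-corrected normal approximation with continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values tied
        return MannWhitneyResult(u_obs, 1.0, "normal_approx")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(2.0 * float(stats.norm.sf(z)), 1.0)
    return MannWhitneyResult(u_obs, p, "normal_approx")


def compare_all(panel: pd.DataFrame) -> list[GroupComparison]:
    """One case/control comparison per parameter in a tidy plasma table.

    Expects columns subject_id, status (case/control), parameter, value and
    optionally units.  Parameters with fewer than 2 subjects in either
    group are reported with method ``untestable`` (summaries only).
    """
    required = {"subject_id", "status", "parameter", "value"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"plasma table missing columns: {sorted(missing)}")
    dup = panel.duplicated(subset=["subject_id", "parameter"])
    if dup.any():
        raise ValueError("duplicate (subject, parameter) measurements in plasma table")

    out: list[GroupComparison] = []
    for param, grp in panel.groupby("parameter", sort=True):
        cases = grp.loc[grp["status"] == "case", "value"].to_numpy(dtype=float)
        controls = grp.loc[grp["status"] == "control", "value"].to_numpy(dtype=float)
        if cases.size == 0 or controls.size == 0:
            continue
        units = str(grp["units"].iloc[0]) if "units" in grp.columns else ""
        case_summary = summarize_group(cases)
        control_summary = summarize_group(controls)
        if cases.size < 2 or controls.size < 2:
            out.append(
                GroupComparison(param, units, case_summary, control_summary, None, None, "untestable")
            )
            continue
        mw = mann_whitney_exact(cases, controls)
        out.append(
            GroupComparison(
                param, units, case_summary, control_summary, mw.U, mw.p_two_sided, mw.method
            )
        )
    return out


def plot_parameter_strips(panel: pd.DataFrame, out_path) -> None:
    """Strip plot of case vs control values, one subplot per parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = sorted(panel["parameter"].unique())
    fig, axes = plt.subplots(1, len(params), figsize=(2.2 * len(params), 3.2), squeeze=False)
    rng = np.random.default_rng(0)  # jitter only
    for ax, param in zip(axes[0], params):
        grp = panel[panel["parameter"] == param]
        for i, status in enumerate(("case", "control")):
            vals = grp.loc[grp["status"] == status, "value"]
            ax.scatter(i + rng.uniform(-0.08, 0.08, len(vals)), vals, s=18, alpha=0.8)
        ax.set_xticks([0, 1], ["case", "control"])
        ax.set_title(param, fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
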