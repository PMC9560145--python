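"""Comparison of counting methods.

Assembles the per-sample count table for the three counting approaches —
manual rapid counting on representative slices (RC), full manual volumetric
counting (VC, the ground truth) and automated counting (AC) — computes
column totals with rates recomputed from the summed counts, and runs the
statistical protocol: Shapiro-Wilk normality screening per method, an
independent two-sample t-test on healthy counts, and the Wilcoxon rank-sum
test (tie-corrected normal approximation, no continuity correction) on
parasitoid counts and rates.

A 12-sample reference table of RC/VC/AC counts ships with the package
(``load_reference_counts``) so the whole comparison is reproducible offline.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .postprocess import CountRecord, round_half_up

METHODS = ("RC", "VC", "AC")
VARIABLES = ("healthy", "parasitoid", "rate")
ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass
class TestReport:
    comparison: str
    test_name: str  # shapiro_wilk | t_independent | wilcoxon_rank_sum
    statistic: float
    p_value: float
    alternative: str = "two_sided"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ComparisonTable:
    """Sample x method count table with totals recomputed from column sums."""

    sample_ids: list[str]
    methods: tuple[str, ...]
    records: dict[str, dict[str, CountRecord]]  # method -> sample_id -> record
    totals: dict[str, CountRecord] = field(default_factory=dict)

    def column(self, method: str, variable: str) -> np.ndarray:
        recs = [self.records[method][s] for s in self.sample_ids]
        if variable == "healthy":
            return np.array([r.healthy for r in recs], dtype=float)
        if variable == "parasitoid":
            return np.array([r.parasitoid for r in recs], dtype=float)
        if variable == "rate":
            vals = [r.parasitoid_rate for r in recs]
            if any(v is None for v in vals):
                raise ValueError("undefined parasitoid rate (healthy count 0) in column")
            return np.array(vals, dtype=float)
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")


def build_table(records_by_method: dict[str, list[CountRecord]]) -> ComparisonTable:
    """Assemble a ComparisonTable; totals' rates come from summed counts,
    never from averaging the per-sample rates."""
    methods = tuple(records_by_method)
    sample_sets = {m: [r.sample_id for r in rs] for m, rs in records_by_method.items()}
    ids = sample_sets[methods[0]]
    for m in methods[1:]:
        if set(sample_sets[m]) != set(ids):
            raise ValueError(f"sample sets differ between methods {methods[0]} and {m}")
    records = {m: {r.sample_id: r for r in rs} for m, rs in records_by_method.items()}
    table = ComparisonTable(sample_ids=list(ids), methods=methods, records=records)
    for m in methods:
        h = sum(r.healthy for r in records[m].values())
        p = sum(r.parasitoid for r in records[m].values())
        table.totals[m] = CountRecord(sample_id="Total", healthy=h, parasitoid=p)
    return table


def load_reference_counts() -> ComparisonTable:
    """The packaged 12-sample RC/VC/AC reference table."""
    text = resources.files("cocoonct").joinpath("data/table1.csv").read_text()
    df = pd.read_csv(_io.StringIO(text), dtype={"sample_id": str})
    by_method: dict[str, list[CountRecord]] = {m: [] for m in METHODS}
    for _, row in df.iterrows():
        for m in METHODS:
            by_method[m].append(CountRecord(sample_id=row["sample_id"],
                                            healthy=int(row[f"{m}_healthy"]),
                                            parasitoid=int(row[f"{m}_parasitoid"])))
    return build_table(by_method)


def normality_screen(columns: dict[str, np.ndarray]) -> list[TestReport]:
    """Shapiro-Wilk test per column; requires n >= 3 per column."""
    reports = []
    for name, values in columns.items():
        values = np.asarray(values, dtype=float)
        if values.size < 3:
            raise ValueError(f"Shapiro-Wilk needs n >= 3, got {values.size} for {name}")
        if np.ptp(values) == 0:
            reports.append(TestReport(comparison=name, test_name="shapiro_wilk",
                                      statistic=float("nan"), p_value=float("nan"),
                                      degenerate=True))
            continue
        w, p = stats.shapiro(values)
        reports.append(TestReport(comparison=name, test_name="shapiro_wilk",
                                  statistic=float(w), p_value=float(p)))
    return reports


def rank_sum_test(x, y, alternative: str = "two_sided",
                  exact: bool = False) -> tuple[float, float]:
    """Wilcoxon rank-sum for two independent samples.

    Returns (W, p) where W is the rank sum of the first sample.  The p-value
    uses the tie-corrected normal approximation without continuity
    correction; ``exact=True`` switches to the exact null distribution
    (small samples, no ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    if exact:
        res = stats.mannwhitneyu(x, y, alternative=ALTERNATIVES[alternative],
                                 method="exact")
        return w, float(res.pvalue)
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        return w, 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    if alternative == "two_sided":
        p = 2.0 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w, float(min(p, 1.0))


def compare_methods(table: ComparisonTable, pair: tuple[str, str], variable: str,
                    alternative: str = "two_sided", welch: bool = False,
                    exact: bool = False) -> TestReport:
    """Two-sample comparison of one variable between two methods.

    Healthy counts use the independent two-sample t-test (pooled variance by
    default, Welch by flag); parasitoid counts and rates use the Wilcoxon
    rank-sum test.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b = (table.column(m, variable) for m in pair)
    label = f"{pair[0]} vs {pair[1]} ({variable})"
    if variable == "healthy":
        res = stats.ttest_ind(a, b, equal_var=not welch,
                              alternative=ALTERNATIVES[alternative])
        return TestReport(comparison=label, test_name="t_independent",
                          statistic=float(res.statistic), p_value=float(res.pvalue),
                          alternative=alternative)
    w, p = rank_sum_test(a, b, alternative=alternative, exact=exact)
    return TestReport(comparison=label, test_name="wilcoxon_rank_sum",
                      statistic=w, p_value=p, alternative=alternative)


def table_to_frame(table: ComparisonTable) -> pd.DataFrame:
    """Wide per-sample frame mirroring the published layout, plus a Total row."""
    rows = []
    for s in table.sample_ids:
        row = {"sample_id": s}
        for m in table.methods:
            r = table.records[m][s]
            row[f"{m}_healthy"] = r.healthy
            row[f"{m}_parasitoid"] = r.parasitoid
            rate = r.parasitoid_rate_display
            row[f"{m}_rate"] = "" if rate is None else f"{rate:.2f}"
        rows.append(row)
    total = {"sample_id": "Total"}
    for m in table.methods:
        r = table.totals[m]
        total[f"{m}_healthy"] = r.healthy
        total[f"{m}_parasitoid"] = r.parasitoid
        rate = r.parasitoid_rate_display
        total[f"{m}_rate"] = "" if rate is None else f"{rate:.2f}"
    rows.append(total)
    cols = (["sample_id"]
            + [f"{m}_healthy" for m in table.methods]
            + [f"{m}_parasitoid" for m in table.methods]
            + [f"{m}_rate" for m in table.methods])
    return pd.DataFrame(rows, columns=cols)


def render_report(table: ComparisonTable, reports: list[TestReport],
                  out_csv: str | None = None) -> str:
    """Render the table plus any test reports; optionally write the CSV."""
    frame = table_to_frame(table)
    csv_text = frame.to_csv(index=False, lineterminator="\n")
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            fh.write(csv_text)
    lines = [csv_text.rstrip("\n")]
    if reports:
        lines.append("")
        lines.append("# statistical tests")
        for r in reports:
            if r.degenerate:
                lines.append(f"{r.comparison}: {r.test_name} degenerate (constant input)")
            else:
                lines.append(f"{r.comparison}: {r.test_name} statistic={r.statistic:.4f} "
                             f"p={r.p_value:.4g} ({r.alternative})")
    return "\n".join(lines) + "\n"
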