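"""The reader-study statistical battery.

Named wrappers around the comparisons the analysis pipeline runs —
independent and paired t-tests (with Cohen's d on the pooled SD),
Wilcoxon signed-rank and Mann-Whitney U with *exact* small-sample null
distributions, and Pearson correlation with its least-squares p-value —
plus :func:`run_full_battery`, which applies them to a study table and
emits a labelled results report.

The exact nonparametric paths are implemented here because ordinal
(Likert) data are riddled with ties and the widely used asymptotic or
tie-free exact routines do not cover that case: the Wilcoxon null is built
by dynamic programming over midranks (zeros dropped first), the
Mann-Whitney null by enumerating all group assignments of the pooled
sample. Both fall back to the usual tie-corrected normal approximation for
larger samples (scipy).

Design notes mirrored from the study being reproduced: across-stage
comparisons of per-participant values use *independent* t-tests even
though the design is paired; the battery reports the paired version
alongside, labelled, for every such comparison. No multiple-testing
correction is applied; the report carries the raw p-values and the number
of tests run.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import StudyTable
from .performance import aggregate_mae_days, mae_days, timing_summary
from .reliance import agreement, log_count_ratio, mean_woa, reliance_proportions

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "independent_t",
    "paired_t",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "pearson_ls",
    "BatteryRow",
    "ResultsReport",
    "run_full_battery",
    "helped_participants",
]

WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 12
HELPED_ITEM = "explanations_helpful"
HELPED_THRESHOLD = 4


class DegenerateDataError(ValueError):
    """The requested statistic is undefined on this input (zero variance,
    all-zero differences, constant series...)."""


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison. ``effect`` is Cohen's d for t-tests,
    the correlation r for pearson_ls, absent otherwise."""

    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    effect: float | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect": self.effect,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    return arr


def independent_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided two-sample t-test with pooled variance; effect is
    Cohen's d = (mean_a - mean_b) / pooled SD."""
    a, b = _as_array(a, "a"), _as_array(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("independent_t needs n >= 2 per group")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        raise DegenerateDataError("zero pooled variance: t and d undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    d = float((a.mean() - b.mean()) / math.sqrt(pooled_var))
    return TestResult("independent_t", float(t), float(p), len(a), len(b), effect=d)


def paired_t(diffs: Sequence[float]) -> TestResult:
    """Two-sided one-sample t-test of the differences against zero mean.
    Effect is Cohen's d_z = mean(diffs)/SD(diffs)."""
    d = _as_array(diffs, "diffs")
    if len(d) < 2:
        raise DegenerateDataError("paired_t needs n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance of differences")
    t, p = stats.ttest_1samp(d, 0.0)
    return TestResult("paired_t", float(t), float(p), len(d), len(d), effect=float(d.mean() / sd))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic under the 2^n
    equiprobable sign assignments, via DP over doubled (integer) midranks."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled W+ equal to s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original procedure). With at
    most 25 nonzero differences the p-value is exact — the full sign-flip
    null on midranks — otherwise the tie-corrected normal approximation is
    used. Raises DegenerateDataError when every difference is zero.
    """
    x, y = _as_array(x, "x"), _as_array(y, "y")
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all differences zero: signed-rank undefined")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        _, p = stats.wilcoxon(d, zero_method="wilcox", correction=False, mode="approx")
        p = float(p)
    return TestResult("wilcoxon", w_plus, p, len(x), len(y))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a > b) pairs + half the ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_mwu_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n_a) assignments of the
    pooled values to group a (ties handled naturally)."""
    n = len(pooled)
    idx = np.arange(n)
    us = []
    for combo in itertools.combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.array(us)
    tol = 1e-9
    cdf = float((us <= u_obs + tol).mean())
    sf = float((us >= u_obs - tol).mean())
    return min(1.0, 2.0 * min(cdf, sf))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U for group ``a``.

    Exact by full enumeration when n_a + n_b <= 12, otherwise the
    tie-corrected normal approximation with continuity correction (scipy).
    """
    a, b = _as_array(a, "a"), _as_array(b, "b")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    u_obs = _u_statistic(a, b)
    if len(a) + len(b) <= MANNWHITNEY_EXACT_MAX_N:
        p = _exact_mwu_p(np.concatenate([a, b]), len(a), u_obs)
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
    return TestResult("mannwhitney", u_obs, p, len(a), len(b))


def pearson_ls(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the two-sided p-value of the least-squares
    slope (the t transform of r with n-2 df). Effect is r itself."""
    x, y = _as_array(x, "x"), _as_array(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise DegenerateDataError("pearson_ls needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult("pearson_ls", float(r), float(p), len(x), len(y), effect=float(r))


# ---------------------------------------------------------------------------
# Battery orchestration


@dataclass(frozen=True)
class BatteryRow:
    """One labelled comparison in the results report. ``result`` is None
    when the comparison could not be computed; ``note`` then carries the
    reason."""

    label: str
    result: TestResult | None
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "result": self.result.as_dict() if self.result else None,
            "note": self.note,
        }


@dataclass
class ResultsReport:
    rows: list[BatteryRow] = field(default_factory=list)
    descriptives: dict = field(default_factory=dict)

    @property
    def n_tests(self) -> int:
        return sum(1 for r in self.rows if r.result is not None)

    def row(self, label: str) -> BatteryRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_json(self) -> str:
        payload = {
            "n_tests": self.n_tests,
            "multiple_testing_correction": "none (raw p-values)",
            "rows": [r.as_dict() for r in self.rows],
            "descriptives": self.descriptives,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [
            "# Reader-study statistical battery",
            "",
            f"{self.n_tests} comparisons computed; raw p-values, no multiple-testing "
            "correction.",
            "",
            "| comparison | method | statistic | p | effect | n |",
            "|---|---|---|---|---|---|",
        ]
        for row in self.rows:
            if row.result is None:
                lines.append(f"| {row.label} | — | — | — | — | — |")
                continue
            t = row.result
            eff = f"{t.effect:.3f}" if t.effect is not None else "—"
            n = f"{t.n_a}" if t.n_a == t.n_b else f"{t.n_a}/{t.n_b}"
            lines.append(
                f"| {row.label} | {t.method} | {t.statistic:.4g} | {t.p_value:.4g} "
                f"| {eff} | {n} |"
            )
        skipped = [r for r in self.rows if r.result is None]
        if skipped:
            lines += ["", "Not computed:", ""]
            lines += [f"- {r.label}: {r.note}" for r in skipped]
        if self.descriptives:
            lines += ["", "## Descriptives", "", "```json",
                      json.dumps(self.descriptives, indent=2, sort_keys=True), "```"]
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "json": out / "results_report.json",
            "md": out / "results_report.md",
        }
        paths["json"].write_text(self.to_json(), encoding="utf-8")
        paths["md"].write_text(self.to_markdown(), encoding="utf-8")
        return paths


def helped_participants(table: StudyTable) -> tuple[list[str], list[str]] | None:
    """Split participants by whether they rated the explanations helpful
    (post-stage-3 Likert >= 4). None when the item is absent."""
    helped, not_helped = [], []
    found = False
    for pid in table.participants():
        v = table.likert_value(pid, "post_stage3", HELPED_ITEM)
        if v is None:
            continue
        found = True
        (helped if v >= HELPED_THRESHOLD else not_helped).append(pid)
    if not found:
        return None
    return helped, not_helped


def _confidence_pairs(table: StudyTable, stage_a: int, stage_b: int):
    df = table.estimates_df()
    a = df[df["stage"] == stage_a].set_index(["participant_id", "image_id"])["confidence"]
    b = df[df["stage"] == stage_b].set_index(["participant_id", "image_id"])["confidence"]
    joined = a.to_frame("a").join(b.to_frame("b"), how="inner")
    return joined["a"].to_numpy(float), joined["b"].to_numpy(float)


def run_full_battery(table: StudyTable) -> ResultsReport:
    """Run every comparison of the study analysis on ``table``.

    Across-stage comparisons of per-participant summaries (MAE, agreement,
    mean WoA, timing) use independent t-tests, mirroring the study design
    being reproduced, with the paired t-test on the same per-participant
    differences reported alongside. Per-estimate confidence uses the
    signed-rank test across stages and the Mann-Whitney U across the
    helped/not-helped split; trust items use participant-paired signed-rank
    tests; reliance-type prevalences are compared via paired t-tests on
    per-participant Haldane log count ratios. A comparison that cannot be
    computed yields a row with an explanatory note, never an exception.
    """
    report = ResultsReport()
    pids = table.participants()

    def add(label: str, fn):
        try:
            report.rows.append(BatteryRow(label, fn()))
        except (DegenerateDataError, ValueError, KeyError) as exc:
            report.rows.append(BatteryRow(label, None, note=f"not computed: {exc}"))

    # --- accuracy -----------------------------------------------------
    mae = {s: np.array([mae_days(table, p, s) for p in pids]) for s in (1, 2, 3)}
    add("MAE stage 1 vs 2 (days)", lambda: independent_t(mae[1], mae[2]))
    add("MAE stage 1 vs 2 (days, paired)", lambda: paired_t(mae[1] - mae[2]))
    add("MAE stage 2 vs 3 (days)", lambda: independent_t(mae[2], mae[3]))
    add("MAE stage 2 vs 3 (days, paired)", lambda: paired_t(mae[2] - mae[3]))

    # --- agreement ----------------------------------------------------
    agr = {s: np.array([agreement(table, p, s) for p in pids]) for s in (1, 2, 3)}
    add("agreement stage 1 vs 2", lambda: independent_t(agr[1], agr[2]))
    add("agreement stage 1 vs 2 (paired)", lambda: paired_t(agr[1] - agr[2]))
    add("agreement stage 2 vs 3", lambda: independent_t(agr[2], agr[3]))
    add("agreement stage 2 vs 3 (paired)", lambda: paired_t(agr[2] - agr[3]))

    # --- weight of advice ---------------------------------------------
    def _woa(stage):
        vals = [mean_woa(table, p, stage).mean for p in pids]
        if any(v is None for v in vals):
            raise DegenerateDataError("a participant had every image excluded")
        return np.array(vals, dtype=float)

    add("mean WoA stage 2 vs 3", lambda: independent_t(_woa(2), _woa(3)))
    add("mean WoA stage 2 vs 3 (paired)", lambda: paired_t(_woa(2) - _woa(3)))

    # --- confidence ---------------------------------------------------
    add(
        "confidence stage 1 vs 2 (per estimate)",
        lambda: wilcoxon_signed_rank(*_confidence_pairs(table, 2, 1)),
    )
    add(
        "confidence stage 2 vs 3 (per estimate)",
        lambda: wilcoxon_signed_rank(*_confidence_pairs(table, 3, 2)),
    )

    split = helped_participants(table)
    df = table.estimates_df()
    for stage in (2, 3):
        def _split_test(stage=stage):
            if split is None:
                raise DegenerateDataError(f"no {HELPED_ITEM!r} responses")
            helped, not_helped = split
            if not helped or not not_helped:
                raise DegenerateDataError("helpfulness split is one-sided")
            sub = df[df["stage"] == stage]
            return mann_whitney_u(
                sub[sub["participant_id"].isin(helped)]["confidence"],
                sub[sub["participant_id"].isin(not_helped)]["confidence"],
            )

        add(f"confidence stage {stage}: helped vs not helped", _split_test)

    # --- trust items --------------------------------------------------
    for item in ("trust", "distrust"):
        def _trust(item=item):
            pairs = [
                (
                    table.likert_value(p, "post_stage2", item),
                    table.likert_value(p, "post_stage3", item),
                )
                for p in pids
            ]
            pairs = [(a, b) for a, b in pairs if a is not None and b is not None]
            if len(pairs) < 2:
                raise DegenerateDataError(f"item {item!r} missing at one timepoint")
            post3 = [b for _, b in pairs]
            post2 = [a for a, _ in pairs]
            return wilcoxon_signed_rank(post3, post2)

        add(f"trust item '{item}' post-stage-2 vs post-stage-3", _trust)

    # --- helpfulness vs performance change ----------------------------
    def _help_vs_dmae():
        xs, ys = [], []
        for p in pids:
            v = table.likert_value(p, "post_stage3", HELPED_ITEM)
            if v is None:
                continue
            xs.append(float(v))
            ys.append(mae_days(table, p, 3) - mae_days(table, p, 2))
        if len(xs) < 3:
            raise DegenerateDataError(f"too few {HELPED_ITEM!r} responses")
        return pearson_ls(xs, ys)

    add("helpfulness rating vs deltaMAE(3-2)", _help_vs_dmae)

    # --- reliance-type prevalence -------------------------------------
    for stage in (2, 3):
        summaries = [reliance_proportions(table, p, stage) for p in pids]
        for name, num, den in (
            ("appropriate vs under", "n_appropriate", "n_under"),
            ("under vs over", "n_under", "n_over"),
        ):
            def _lr(summaries=summaries, num=num, den=den):
                lr = [
                    log_count_ratio(getattr(s, num), getattr(s, den)) for s in summaries
                ]
                res = paired_t(lr)
                return TestResult(
                    "log_ratio_t", res.statistic, res.p_value, res.n_a, res.n_b, res.effect
                )

            add(f"log ratio {name}, stage {stage}", _lr)

    # --- clinical-practice comfort ------------------------------------
    def _comfort():
        pairs = [
            (
                table.likert_value(p, "pre_study", "comfort_practice"),
                table.likert_value(p, "post_study", "comfort_practice"),
            )
            for p in pids
        ]
        pairs = [(a, b) for a, b in pairs if a is not None and b is not None]
        if len(pairs) < 2:
            raise DegenerateDataError("comfort_practice missing at a timepoint")
        return wilcoxon_signed_rank([b for _, b in pairs], [a for a, _ in pairs])

    add("comfort incorporating model: pre vs post study", _comfort)

    # --- timing -------------------------------------------------------
    time_mean = {
        s: df[df["stage"] == s].groupby("participant_id")["time_sec"].mean().reindex(pids)
        for s in (2, 3)
    }
    add(
        "time per estimate stage 2 vs 3 (s)",
        lambda: independent_t(time_mean[2].to_numpy(), time_mean[3].to_numpy()),
    )
    add(
        "time per estimate stage 2 vs 3 (s, paired)",
        lambda: paired_t(time_mean[2].to_numpy() - time_mean[3].to_numpy()),
    )

    # --- descriptives -------------------------------------------------
    report.descriptives = {
        "mae_days": {str(s): aggregate_mae_days(table, s) for s in (1, 2, 3)},
        "agreement": {
            str(s): {
                "mean": float(agr[s].mean()),
                "sd": float(agr[s].std(ddof=1)) if len(agr[s]) > 1 else None,
            }
            for s in (1, 2, 3)
        },
        "timing_sec": {
            str(s): {
                "mean": timing_summary(table, s).mean_sec,
                "sd": timing_summary(table, s).sd_sec,
                "comparable": timing_summary(table, s).comparable,
            }
            for s in (1, 2, 3)
        },
    }
    return report
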