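"""Domain types and CSV I/O for three-stage reader-study tables.

A reader study presents each participant with the same set of ultrasound
images in three stages: stage 1 unaided, stage 2 with the model's
gestational-age (GA) prediction, stage 3 with the prediction plus its
explanation. The model predicts GA as one of 13 contiguous bins spanning
13-42 weeks (interior bins exactly 2 weeks wide, the first and last wider
because the extremes of the GA range are sparsely sampled); a scalar point
value inside the bin represents the prediction where a single number is
needed.

All GA quantities are carried internally in weeks (fractional allowed);
days appear only in reported mean absolute errors (x7).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GA_RANGE_WEEKS",
    "STAGES",
    "TIMEPOINTS",
    "GABin",
    "BinScheme",
    "ModelPrediction",
    "EstimateRecord",
    "LikertResponse",
    "StudyTable",
    "StudyValidationError",
    "CSVParseError",
    "default_bin_scheme",
    "read_study_csv",
    "write_study_csv",
]

GA_RANGE_WEEKS = (13.0, 42.0)
ESTIMATE_RANGE_WEEKS = (10.0, 45.0)
STAGES = (1, 2, 3)
TIMEPOINTS = ("pre_study", "post_stage2", "post_stage3", "post_study")


class StudyValidationError(ValueError):
    """An invariant of the study data model was violated.

    ``rule`` names the violated invariant so callers (and CLI users) can
    see which check failed without parsing the message.
    """

    def __init__(self, rule: str, detail: str):
        self.rule = rule
        self.detail = detail
        super().__init__(f"[{rule}] {detail}")


class CSVParseError(ValueError):
    """A CSV row could not be parsed into a record. Carries the 1-based
    data-row number."""

    def __init__(self, path: str | Path, row: int | None, detail: str):
        self.path = str(path)
        self.row = row
        where = f"{path}" if row is None else f"{path}, data row {row}"
        super().__init__(f"{where}: {detail}")


def _check(cond: bool, rule: str, detail: str) -> None:
    if not cond:
        raise StudyValidationError(rule, detail)


@dataclass(frozen=True)
class GABin:
    """A half-open GA interval [lo, hi) in weeks (the scheme's last bin is
    treated as closed on the right so the full range is covered)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        _check(self.lo < self.hi, "bin.ordered", f"lo={self.lo} !< hi={self.hi}")
        _check(
            GA_RANGE_WEEKS[0] <= self.lo and self.hi <= GA_RANGE_WEEKS[1],
            "bin.range",
            f"[{self.lo}, {self.hi}] outside GA range {GA_RANGE_WEEKS}",
        )
        _check(self.width >= 2.0, "bin.width", f"width {self.width} < 2 weeks")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def contains(self, ga_weeks: float, *, closed_right: bool = False) -> bool:
        if closed_right:
            return self.lo <= ga_weeks <= self.hi
        return self.lo <= ga_weeks < self.hi


@dataclass(frozen=True)
class BinScheme:
    """The ordered, contiguous 13-bin discretisation of the 13-42 week GA
    range used by the prediction model."""

    bins: tuple[GABin, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(self.bins))
        b = self.bins
        _check(len(b) == 13, "scheme.count", f"expected 13 bins, got {len(b)}")
        for prev, nxt in zip(b, b[1:]):
            _check(
                prev.hi == nxt.lo,
                "scheme.contiguous",
                f"gap/overlap between [{prev.lo},{prev.hi}) and [{nxt.lo},{nxt.hi})",
            )
        _check(
            b[0].lo == GA_RANGE_WEEKS[0] and b[-1].hi == GA_RANGE_WEEKS[1],
            "scheme.cover",
            f"bins span [{b[0].lo}, {b[-1].hi}], expected {GA_RANGE_WEEKS}",
        )
        for inner in b[1:-1]:
            _check(
                inner.width == 2.0,
                "scheme.interior_width",
                f"interior bin [{inner.lo},{inner.hi}) is not 2 weeks wide",
            )
        _check(
            b[0].width > 2.0 and b[-1].width > 2.0,
            "scheme.outer_width",
            "first and last bins must be wider than 2 weeks",
        )

    def __iter__(self):
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    def bin_for(self, ga_weeks: float) -> GABin:
        """Map a GA value to its unique bin (half-open; last bin closed)."""
        for b in self.bins[:-1]:
            if b.contains(ga_weeks):
                return b
        last = self.bins[-1]
        if last.contains(ga_weeks, closed_right=True):
            return last
        raise ValueError(f"GA {ga_weeks} weeks outside binned range {GA_RANGE_WEEKS}")

    def is_last(self, b: GABin) -> bool:
        return b == self.bins[-1]

    def membership(self, b: GABin, ga_weeks: float) -> bool:
        """Whether ``ga_weeks`` falls in bin ``b`` under the scheme's
        convention (half-open, last bin closed)."""
        return b.contains(ga_weeks, closed_right=self.is_last(b))


def default_bin_scheme() -> BinScheme:
    """Canonical 13-bin scheme: [13,16), eleven 2-week bins [16,18)...[36,38),
    and [38,42]. One consistent realisation of "13 bins of ~2 weeks with
    wider outer bins"; override by constructing a BinScheme directly."""
    edges = [13.0, 16.0] + [18.0 + 2.0 * i for i in range(11)] + [42.0]
    return BinScheme(tuple(GABin(lo, hi) for lo, hi in zip(edges, edges[1:])))


@dataclass(frozen=True)
class ModelPrediction:
    """The model's binned GA prediction for one image plus the scalar point
    value (default convention: the bin midpoint) standing in for it in
    arithmetic such as Weight of Advice."""

    image_id: str
    bin: GABin
    point_weeks: float

    def __post_init__(self) -> None:
        _check(
            self.bin.lo <= self.point_weeks <= self.bin.hi,
            "prediction.point_in_bin",
            f"point {self.point_weeks} outside bin [{self.bin.lo}, {self.bin.hi}]",
        )


@dataclass(frozen=True)
class EstimateRecord:
    """One participant's GA estimate for one image at one stage."""

    participant_id: str
    image_id: str
    stage: int
    true_ga_weeks: float
    estimate_weeks: float
    confidence: int
    time_sec: float
    features: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", frozenset(self.features))
        _check(self.stage in STAGES, "estimate.stage", f"stage {self.stage} not in {STAGES}")
        _check(
            ESTIMATE_RANGE_WEEKS[0] <= self.estimate_weeks <= ESTIMATE_RANGE_WEEKS[1],
            "estimate.range",
            f"estimate {self.estimate_weeks} weeks outside {ESTIMATE_RANGE_WEEKS}",
        )
        _check(
            GA_RANGE_WEEKS[0] <= self.true_ga_weeks <= GA_RANGE_WEEKS[1],
            "estimate.truth_range",
            f"true GA {self.true_ga_weeks} weeks outside {GA_RANGE_WEEKS}",
        )
        _check(
            self.confidence in (1, 2, 3, 4, 5),
            "estimate.confidence",
            f"confidence {self.confidence} not in 1..5",
        )
        _check(self.time_sec >= 0, "estimate.time", f"time {self.time_sec} s negative")
        _check(
            self.stage == 1 or not self.features,
            "estimate.features_stage1_only",
            f"features present at stage {self.stage}",
        )


@dataclass(frozen=True)
class LikertResponse:
    """One 1-5 Likert answer to a questionnaire item at a study timepoint."""

    participant_id: str
    timepoint: str
    item_id: str
    value: int

    def __post_init__(self) -> None:
        _check(
            self.timepoint in TIMEPOINTS,
            "likert.timepoint",
            f"timepoint {self.timepoint!r} not in {TIMEPOINTS}",
        )
        _check(self.value in (1, 2, 3, 4, 5), "likert.value", f"value {self.value} not in 1..5")


@dataclass
class StudyTable:
    """A complete, validated reader study: estimates for all participants
    across all three stages, one model prediction per image, questionnaire
    responses, and the bin scheme the predictions use."""

    estimates: list[EstimateRecord]
    predictions: list[ModelPrediction]
    likert: list[LikertResponse] = field(default_factory=list)
    bin_scheme: BinScheme = field(default_factory=default_bin_scheme)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for r in self.estimates:
            key = (r.participant_id, r.image_id, r.stage)
            _check(key not in seen, "table.unique_key", f"duplicate record {key}")
            seen.add(key)

        pred_images: dict[str, ModelPrediction] = {}
        for p in self.predictions:
            _check(
                p.image_id not in pred_images,
                "table.one_prediction_per_image",
                f"duplicate prediction for image {p.image_id}",
            )
            pred_images[p.image_id] = p

        est_images = {r.image_id for r in self.estimates}
        missing = est_images - set(pred_images)
        _check(
            not missing,
            "table.prediction_coverage",
            f"images without a model prediction: {sorted(missing)[:5]}",
        )

        by_participant: dict[str, dict[int, set[str]]] = {}
        for r in self.estimates:
            by_participant.setdefault(r.participant_id, {}).setdefault(r.stage, set()).add(
                r.image_id
            )
        for pid, stages in by_participant.items():
            _check(
                set(stages) == set(STAGES),
                "table.all_stages",
                f"participant {pid} has stages {sorted(stages)}, expected {list(STAGES)}",
            )
            imgs = [stages[s] for s in STAGES]
            _check(
                imgs[0] == imgs[1] == imgs[2],
                "table.same_images_per_stage",
                f"participant {pid} has differing image sets across stages",
            )

    # -- convenience views ---------------------------------------------

    def participants(self) -> list[str]:
        return sorted({r.participant_id for r in self.estimates})

    def images(self) -> list[str]:
        return sorted({r.image_id for r in self.estimates})

    def prediction_for(self, image_id: str) -> ModelPrediction:
        return self._pred_map()[image_id]

    def _pred_map(self) -> Mapping[str, ModelPrediction]:
        cached = getattr(self, "_pred_cache", None)
        if cached is None:
            cached = {p.image_id: p for p in self.predictions}
            self._pred_cache = cached
        return cached

    def estimates_df(self) -> pd.DataFrame:
        cached = getattr(self, "_est_df", None)
        if cached is None:
            cached = pd.DataFrame(
                {
                    "participant_id": [r.participant_id for r in self.estimates],
                    "image_id": [r.image_id for r in self.estimates],
                    "stage": [r.stage for r in self.estimates],
                    "true_ga_weeks": [r.true_ga_weeks for r in self.estimates],
                    "estimate_weeks": [r.estimate_weeks for r in self.estimates],
                    "confidence": [r.confidence for r in self.estimates],
                    "time_sec": [r.time_sec for r in self.estimates],
                    "n_features": [len(r.features) for r in self.estimates],
                }
            )
            self._est_df = cached
        return cached

    def likert_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.likert],
                "timepoint": [r.timepoint for r in self.likert],
                "item_id": [r.item_id for r in self.likert],
                "value": [r.value for r in self.likert],
            }
        )

    def likert_value(self, participant_id: str, timepoint: str, item_id: str) -> int | None:
        for r in self.likert:
            if (
                r.participant_id == participant_id
                and r.timepoint == timepoint
                and r.item_id == item_id
            ):
                return r.value
        return None


# -- CSV I/O -----------------------------------------------------------

_EST_COLS = [
    "participant_id",
    "image_id",
    "stage",
    "true_ga_weeks",
    "estimate_weeks",
    "confidence",
    "time_sec",
    "features",
]
_PRED_COLS = ["image_id", "bin_lo_weeks", "bin_hi_weeks", "point_weeks"]
_LIK_COLS = ["participant_id", "timepoint", "item_id", "value"]


def _read_csv(path: str | Path, cols: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CSVParseError(path, None, "file not found")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV structure
        raise CSVParseError(path, None, f"unreadable CSV: {exc}") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CSVParseError(path, None, f"missing columns {missing}")
    return df


def read_study_csv(
    path_estimates: str | Path,
    path_predictions: str | Path,
    path_likert: str | Path | None = None,
    *,
    bin_scheme: BinScheme | None = None,
) -> StudyTable:
    """Read and validate a study from the three CSV files.

    ``bin_scheme`` defaults to the canonical scheme; every prediction's bin
    must belong to it. A malformed row raises :class:`CSVParseError` naming
    the data-row number; a violated invariant raises
    :class:`StudyValidationError` naming the rule.
    """
    scheme = bin_scheme or default_bin_scheme()

    df_e = _read_csv(path_estimates, _EST_COLS)
    estimates: list[EstimateRecord] = []
    for i, row in enumerate(df_e.itertuples(index=False), start=1):
        try:
            feats = frozenset(t for t in str(row.features).split(";") if t)
            estimates.append(
                EstimateRecord(
                    participant_id=str(row.participant_id),
                    image_id=str(row.image_id),
                    stage=int(row.stage),
                    true_ga_weeks=float(row.true_ga_weeks),
                    estimate_weeks=float(row.estimate_weeks),
                    confidence=int(row.confidence),
                    time_sec=float(row.time_sec),
                    features=feats,
                )
            )
        except StudyValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise CSVParseError(path_estimates, i, str(exc)) from exc

    df_p = _read_csv(path_predictions, _PRED_COLS)
    scheme_bins = {(b.lo, b.hi): b for b in scheme}
    predictions: list[ModelPrediction] = []
    for i, row in enumerate(df_p.itertuples(index=False), start=1):
        try:
            lo, hi = float(row.bin_lo_weeks), float(row.bin_hi_weeks)
        except (TypeError, ValueError) as exc:
            raise CSVParseError(path_predictions, i, str(exc)) from exc
        if (lo, hi) not in scheme_bins:
            raise StudyValidationError(
                "prediction.bin_in_scheme",
                f"bin [{lo}, {hi}] (row {i}) not in the bin scheme",
            )
        try:
            predictions.append(
                ModelPrediction(
                    image_id=str(row.image_id),
                    bin=scheme_bins[(lo, hi)],
                    point_weeks=float(row.point_weeks),
                )
            )
        except StudyValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise CSVParseError(path_predictions, i, str(exc)) from exc

    likert: list[LikertResponse] = []
    if path_likert is not None:
        df_l = _read_csv(path_likert, _LIK_COLS)
        for i, row in enumerate(df_l.itertuples(index=False), start=1):
            try:
                likert.append(
                    LikertResponse(
                        participant_id=str(row.participant_id),
                        timepoint=str(row.timepoint),
                        item_id=str(row.item_id),
                        value=int(row.value),
                    )
                )
            except StudyValidationError:
                raise
            except (TypeError, ValueError) as exc:
                raise CSVParseError(path_likert, i, str(exc)) from exc

    return StudyTable(estimates, predictions, likert, scheme)


def write_study_csv(table: StudyTable, out_dir: str | Path) -> dict[str, Path]:
    """Write estimates.csv / predictions.csv / likert.csv to ``out_dir``.

    Rows are sorted deterministically so identical tables produce
    byte-identical files; ``read_study_csv`` on the output reproduces the
    table exactly (floats are written with full round-trip precision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "estimates": out / "estimates.csv",
        "predictions": out / "predictions.csv",
        "likert": out / "likert.csv",
    }

    est = sorted(table.estimates, key=lambda r: (r.participant_id, r.image_id, r.stage))
    with open(paths["estimates"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_EST_COLS) + "\n")
        for r in est:
            feats = ";".join(sorted(r.features))
            fh.write(
                f"{r.participant_id},{r.image_id},{r.stage},{r.true_ga_weeks!r},"
                f"{r.estimate_weeks!r},{r.confidence},{r.time_sec!r},{feats}\n"
            )

    preds = sorted(table.predictions, key=lambda p: p.image_id)
    with open(paths["predictions"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_PRED_COLS) + "\n")
        for p in preds:
            fh.write(f"{p.image_id},{p.bin.lo!r},{p.bin.hi!r},{p.point_weeks!r}\n")

    tp_order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    lik = sorted(
        table.likert, key=lambda r: (r.participant_id, tp_order[r.timepoint], r.item_id)
    )
    with open(paths["likert"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_LIK_COLS) + "\n")
        for r in lik:
            fh.write(f"{r.participant_id},{r.timepoint},{r.item_id},{r.value}\n")

    return paths
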