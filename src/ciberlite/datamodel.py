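"""Domain types for lean determinant measurement.

A determinant study measures a small set of psychological constructs
(determinants such as attitude, perceived norm, and perceived behavioral
control) with one item per facet (subdeterminant), plus a single target
item (typically behavioral intention), all on a short Likert scale.
This module holds the instrument description, the respondent-by-item
score matrix, scoring helpers, and CSV / YAML I/O.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LikertScale",
    "ItemSpec",
    "InstrumentSpec",
    "ResponseDataset",
    "DeterminantBlock",
    "DeterminantSummary",
    "ExpertEstimateSet",
    "raa_instrument",
    "load_responses",
    "validate_responses",
    "score_composite",
    "room_for_improvement",
    "load_instrument",
    "save_instrument",
    "load_expert_estimates",
]

#: Placeholder token in item templates: a literal ``X`` on word boundaries.
_PLACEHOLDER = re.compile(r"\bX\b")


@dataclass(frozen=True)
class LikertScale:
    """Integer response scale with inclusive bounds (e.g. 1..5)."""

    minimum: int = 1
    maximum: int = 5

    def __post_init__(self) -> None:
        if self.maximum <= self.minimum:
            raise ValueError(
                f"scale maximum ({self.maximum}) must exceed minimum ({self.minimum})"
            )

    @property
    def n_points(self) -> int:
        return self.maximum - self.minimum + 1

    def contains(self, value: float) -> bool:
        return self.minimum <= value <= self.maximum


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item.

    ``text_template`` contains exactly one literal ``X`` (on word
    boundaries) that is replaced by the behavior of interest.
    """

    item_id: str
    text_template: str
    subdeterminant: str
    anchors: tuple[str, str]
    reverse_coded: bool = False

    def __post_init__(self) -> None:
        n = len(_PLACEHOLDER.findall(self.text_template))
        if n != 1:
            raise ValueError(
                f"item {self.item_id!r}: template must contain exactly one "
                f"'X' placeholder, found {n}"
            )

    def render(self, behavior_label: str) -> str:
        """Item text with the behavior substituted for the placeholder."""
        return _PLACEHOLDER.sub(behavior_label, self.text_template)


@dataclass(frozen=True)
class InstrumentSpec:
    """A determinant hierarchy for one behavior.

    ``determinants`` is an ordered list of ``(label, items)`` pairs; the
    ``target`` item (e.g. intention) stands outside the hierarchy.
    """

    behavior_label: str
    scale: LikertScale
    determinants: tuple[tuple[str, tuple[ItemSpec, ...]], ...]
    target: ItemSpec

    def __post_init__(self) -> None:
        if not self.determinants:
            raise ValueError("instrument needs at least one determinant")
        ids: list[str] = []
        for label, items in self.determinants:
            if not items:
                raise ValueError(f"determinant {label!r} has no items")
            ids.extend(item.item_id for item in items)
        if self.target.item_id in ids:
            raise ValueError("target item must not appear under a determinant")
        ids.append(self.target.item_id)
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate item ids: {sorted(dupes)}")

    @property
    def item_ids(self) -> list[str]:
        """All item ids, determinant items first, target last."""
        out = [it.item_id for _, items in self.determinants for it in items]
        out.append(self.target.item_id)
        return out

    @property
    def determinant_labels(self) -> list[str]:
        return [label for label, _ in self.determinants]

    def items_of(self, determinant_label: str) -> tuple[ItemSpec, ...]:
        for label, items in self.determinants:
            if label == determinant_label:
                return items
        raise KeyError(determinant_label)

    def rendered_items(self) -> dict[str, str]:
        """item_id -> item text with the behavior filled in."""
        out = {
            it.item_id: it.render(self.behavior_label)
            for _, items in self.determinants
            for it in items
        }
        out[self.target.item_id] = self.target.render(self.behavior_label)
        return out


@dataclass
class ResponseDataset:
    """Respondent x item integer score matrix on a declared scale.

    ``n_excluded`` counts rows dropped during validation (listwise:
    any missing or out-of-range value in a required column removes the
    whole respondent).
    """

    respondent_ids: list[str]
    columns: list[str]
    scores: np.ndarray
    scale: LikertScale
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.shape != (len(self.respondent_ids), len(self.columns)):
            raise ValueError("score matrix shape does not match ids/columns")
        if self.scores.size and (
            self.scores.min() < self.scale.minimum
            or self.scores.max() > self.scale.maximum
        ):
            raise ValueError("scores outside the declared scale bounds")

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    def column(self, item_id: str) -> np.ndarray:
        try:
            j = self.columns.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item id {item_id!r}") from None
        return self.scores[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, columns=self.columns, index=pd.Index(self.respondent_ids, name="respondent")
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class DeterminantBlock:
    """Per-determinant slice of a summary: means plus the target correlation."""

    label: str
    generic_mean: float
    item_means: tuple[tuple[str, float], ...]  # (subdeterminant label, mean)
    correlation: "object"  # CorrelationResult (kept untyped to avoid a cycle)


@dataclass(frozen=True)
class DeterminantSummary:
    """Data contract of a CIBERlite plot for one behavior."""

    behavior_label: str
    scale: LikertScale
    blocks: tuple[DeterminantBlock, ...]
    n: int

    def __post_init__(self) -> None:
        for b in self.blocks:
            means = [b.generic_mean] + [m for _, m in b.item_means]
            for m in means:
                if not self.scale.contains(m):
                    raise ValueError(
                        f"{b.label}: mean {m} outside scale "
                        f"[{self.scale.minimum}, {self.scale.maximum}]"
                    )


@dataclass
class ExpertEstimateSet:
    """Expert x (behavior, determinant) matrix of integer 1-5 estimates."""

    expert_ids: list[str]
    cells: list[tuple[str, str]]  # (behavior, determinant)
    values: np.ndarray
    scale: LikertScale = field(default_factory=LikertScale)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.expert_ids), len(self.cells)):
            raise ValueError("estimate matrix shape does not match experts/cells")
        if self.values.size and (
            self.values.min() < self.scale.minimum
            or self.values.max() > self.scale.maximum
        ):
            raise ValueError("estimates outside the declared scale bounds")

    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.cells, names=["behavior", "determinant"])
        return pd.DataFrame(self.values, index=pd.Index(self.expert_ids, name="expert"), columns=cols)

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.columns = [f"{b}|{d}" for b, d in frame.columns]
        frame.to_csv(path)


# ---------------------------------------------------------------------------
# Instrument template


def raa_instrument(behavior_label: str, scale: LikertScale | None = None) -> InstrumentSpec:
    """The seven-item Reasoned Action Approach short instrument.

    Three generic determinants with two single-item facets each —
    attitude (instrumental, experiential), perceived norm (injunctive,
    descriptive), perceived behavioral control (capacity, autonomy) —
    plus a single intention target item, all on a 5-point scale.
    """
    if not behavior_label or not behavior_label.strip():
        raise ValueError("behavior label must be non-empty")
    scale = scale or LikertScale(1, 5)

    def item(iid: str, text: str, sub: str, lo: str, hi: str) -> ItemSpec:
        return ItemSpec(item_id=iid, text_template=text, subdeterminant=sub, anchors=(lo, hi))

    determinants = (
        (
            "attitude",
            (
                item("att_instrumental", "For me, X is ...", "instrumental", "Bad", "Good"),
                item("att_experiential", "For me, X is ...", "experiential", "Unpleasant", "Pleasant"),
            ),
        ),
        (
            "perceived_norm",
            (
                item(
                    "pn_injunctive",
                    "If I do X, then most people that are important to me would ... of this",
                    "injunctive",
                    "Disapprove",
                    "Approve",
                ),
                item("pn_descriptive", "How many people like you do X?", "descriptive", "Nobody", "Everybody"),
            ),
        ),
        (
            "pbc",
            (
                item("pbc_capacity", "I'm confident that, if I want to, I can do X", "capacity", "No confidence at all", "Very confident"),
                item("pbc_autonomy", "Whether I do X is ...", "autonomy", "Not up to me", "Completely up to me"),
            ),
        ),
    )
    target = ItemSpec(
        item_id="intention",
        text_template="I intend to do X",
        subdeterminant="intention",
        anchors=("Absolutely not", "Absolutely"),
    )
    return InstrumentSpec(
        behavior_label=behavior_label.strip(),
        scale=scale,
        determinants=determinants,
        target=target,
    )


# ---------------------------------------------------------------------------
# Response I/O and validation


def validate_responses(
    frame: pd.DataFrame, spec: InstrumentSpec, id_column: str | None = None
) -> ResponseDataset:
    """Validate a raw wide table against an instrument.

    Rows with any missing, non-integer, or out-of-range value in the
    instrument's columns are excluded listwise and counted.
    """
    required = spec.item_ids
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    if id_column is not None and id_column in frame.columns:
        ids = frame[id_column].astype(str).tolist()
    elif "respondent" in frame.columns:
        ids = frame["respondent"].astype(str).tolist()
    else:
        ids = [str(i) for i in frame.index]

    raw = frame[required].apply(pd.to_numeric, errors="coerce")
    is_int = raw.notna() & (np.mod(raw.fillna(0.5), 1) == 0)
    in_range = raw.ge(spec.scale.minimum) & raw.le(spec.scale.maximum)
    keep = (is_int & in_range).all(axis=1).to_numpy()

    scores = raw.loc[keep].to_numpy(dtype=np.int64)
    kept_ids = [i for i, k in zip(ids, keep) if k]
    return ResponseDataset(
        respondent_ids=kept_ids,
        columns=list(required),
        scores=scores,
        scale=spec.scale,
        n_excluded=int((~keep).sum()),
    )


def load_responses(path: str | Path, spec: InstrumentSpec) -> ResponseDataset:
    """Read a wide CSV (header row mandatory) and validate it."""
    try:
        frame = pd.read_csv(path)
    except OSError as exc:
        raise ValueError(f"cannot read response file {path}: {exc}") from exc
    return validate_responses(frame, spec)


def load_expert_estimates(path: str | Path, scale: LikertScale | None = None) -> ExpertEstimateSet:
    """Read expert estimates from CSV with ``behavior|determinant`` columns."""
    frame = pd.read_csv(path, index_col=0)
    cells = []
    for col in frame.columns:
        if "|" not in col:
            raise ValueError(f"expert column {col!r} is not 'behavior|determinant'")
        b, d = col.split("|", 1)
        cells.append((b, d))
    return ExpertEstimateSet(
        expert_ids=[str(i) for i in frame.index],
        cells=cells,
        values=frame.to_numpy(dtype=np.int64),
        scale=scale or LikertScale(),
    )


# ---------------------------------------------------------------------------
# Scoring


def score_composite(dataset: ResponseDataset, item_ids: Sequence[str]) -> np.ndarray:
    """Per-respondent unweighted mean of the listed items, in scale units.

    Reverse-coded items must be recoded upstream; composites here are
    plain arithmetic means, matching the equal-weighting convention for
    generic-determinant scores.
    """
    if not item_ids:
        raise ValueError("need at least one item id")
    cols = np.column_stack([dataset.column(i) for i in item_ids])
    return cols.mean(axis=1)


def reverse_code(scores: np.ndarray, scale: LikertScale) -> np.ndarray:
    """Mirror scores around the scale midpoint (min+max-x)."""
    return scale.minimum + scale.maximum - np.asarray(scores)


def room_for_improvement(mean: float, scale: LikertScale) -> float:
    """Distance from a mean to the desirable scale ceiling.

    Assumes higher is desired; reverse-code first if not. A large value
    marks a promising intervention target.
    """
    if not scale.contains(mean):
        raise ValueError(
            f"mean {mean} outside scale [{scale.minimum}, {scale.maximum}]"
        )
    return float(scale.maximum - mean)


# ---------------------------------------------------------------------------
# Instrument config I/O (YAML)


def save_instrument(spec: InstrumentSpec, path: str | Path) -> None:
    doc = {
        "behavior_label": spec.behavior_label,
        "scale": {"minimum": spec.scale.minimum, "maximum": spec.scale.maximum},
        "determinants": [
            {
                "label": label,
                "items": [
                    {
                        "item_id": it.item_id,
                        "text_template": it.text_template,
                        "subdeterminant": it.subdeterminant,
                        "anchors": list(it.anchors),
                        "reverse_coded": it.reverse_coded,
                    }
                    for it in items
                ],
            }
            for label, items in spec.determinants
        ],
        "target": {
            "item_id": spec.target.item_id,
            "text_template": spec.target.text_template,
            "subdeterminant": spec.target.subdeterminant,
            "anchors": list(spec.target.anchors),
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _item_from_dict(d: dict) -> ItemSpec:
    return ItemSpec(
        item_id=d["item_id"],
        text_template=d["text_template"],
        subdeterminant=d.get("subdeterminant", ""),
        anchors=tuple(d.get("anchors", ("low", "high"))),
        reverse_coded=bool(d.get("reverse_coded", False)),
    )


def load_instrument(path: str | Path) -> InstrumentSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return InstrumentSpec(
        behavior_label=doc["behavior_label"],
        scale=LikertScale(**doc["scale"]),
        determinants=tuple(
            (d["label"], tuple(_item_from_dict(i) for i in d["items"]))
            for d in doc["determinants"]
        ),
        target=_item_from_dict(doc["target"]),
    )
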