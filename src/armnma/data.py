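"""Long-format arm-level data structures for network meta-analysis.

The atomic record is one trial *arm*: a study label, a treatment label and a
binomial event count ``r`` out of ``n`` subjects.  A :class:`NmaDataset` is a
validated collection of arms together with the treatment coding (reference
treatment first) and the derived per-arm trial/treatment indices the models
consume.  The "long and narrow" layout — one row per arm — keeps the table's
shape independent of how many arms each trial has, and would extend naturally
to one row per patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ArmRecord",
    "TreatmentCoding",
    "NmaDataset",
    "NetworkSummary",
    "load_long_table",
    "remove_studies",
    "network_summary",
]

REQUIRED_COLUMNS = ("study", "treatment", "events", "size")


class DataError(ValueError):
    """Arm-level input data violate the requirements of the models."""


def _as_int(value, what: str, context: str) -> int:
    """Coerce ``value`` to a non-bool integer, rejecting fractional floats."""
    if isinstance(value, bool):
        raise DataError(f"{what} must be an integer, got boolean ({context})")
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        if float(value).is_integer():
            return int(value)
        raise DataError(f"{what} must be an integer, got {value!r} ({context})")
    try:
        text = str(value).strip()
        return int(text)
    except (TypeError, ValueError):
        raise DataError(f"{what} must be an integer, got {value!r} ({context})") from None


@dataclass(frozen=True)
class ArmRecord:
    """One trial arm: ``events`` successes out of ``size`` subjects."""

    study: str
    treatment: str
    events: int
    size: int

    def __post_init__(self) -> None:
        context = f"study={self.study!r}, treatment={self.treatment!r}"
        object.__setattr__(self, "study", str(self.study))
        object.__setattr__(self, "treatment", str(self.treatment))
        object.__setattr__(self, "events", _as_int(self.events, "events", context))
        object.__setattr__(self, "size", _as_int(self.size, "size", context))
        if self.size < 1:
            raise DataError(f"size must be >= 1, got {self.size} ({context})")
        if not 0 <= self.events <= self.size:
            raise DataError(
                f"events must satisfy 0 <= events <= size, got "
                f"events={self.events}, size={self.size} ({context})"
            )


@dataclass(frozen=True)
class TreatmentCoding:
    """Ordered treatment labels; the first label is the network reference.

    Positions are exposed 1-based (``index(reference) == 1``) to match the
    convention that treatment 1 is the overall reference.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise DataError("treatment coding requires at least one label")
        if len(set(labels)) != len(labels):
            raise DataError(f"treatment labels must be unique, got {labels}")

    @property
    def reference(self) -> str:
        return self.labels[0]

    @property
    def n_treatments(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """1-based index of ``label``; the reference treatment has index 1."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise DataError(f"unknown treatment label {label!r}") from None

    def label(self, index: int) -> str:
        """Label of the 1-based treatment ``index``."""
        if not 1 <= index <= len(self.labels):
            raise DataError(f"treatment index {index} out of range 1..{len(self.labels)}")
        return self.labels[index - 1]


@dataclass(frozen=True)
class NetworkSummary:
    """Direct-comparison counts per treatment pair and per-treatment totals."""

    pair_trials: Mapping[tuple[str, str], int]
    treatment_events: Mapping[str, int]
    treatment_size: Mapping[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"treatment_a": a, "treatment_b": b, "n_trials": c}
            for (a, b), c in self.pair_trials.items()
        ]
        return pd.DataFrame(rows, columns=["treatment_a", "treatment_b", "n_trials"])

    def to_json_dict(self) -> dict:
        return {
            "pairs": [
                {"treatments": [a, b], "n_trials": c}
                for (a, b), c in self.pair_trials.items()
            ],
            "treatments": [
                {
                    "treatment": t,
                    "events": self.treatment_events[t],
                    "size": self.treatment_size[t],
                }
                for t in self.treatment_events
            ],
        }

    def write(self, csv_path: str | Path | None = None, json_path: str | Path | None = None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_json_dict(), indent=2))


class NmaDataset:
    """Validated network meta-analysis dataset in long (one row per arm) form.

    Arms are stored in canonical order: trials in order of first appearance in
    the input, arms within a trial in ascending treatment index.  All derived
    indices are therefore invariant to the row order of the input table.

    Attributes
    ----------
    arms : tuple of ArmRecord
        Canonically ordered arms.
    coding : TreatmentCoding
        Treatment labels, reference first.
    studies : tuple of str
        Study labels in order of first appearance.
    study_index, treatment_index : ndarray of int
        0-based trial ``s[i]`` and treatment ``t[i]`` per arm.
    trial_base_treatment : ndarray of int
        0-based base treatment ``b[j]`` per trial (lowest treatment index
        present in the trial).
    """

    def __init__(self, arms: Iterable[ArmRecord], coding: TreatmentCoding):
        arms = tuple(arms)
        if not arms:
            raise DataError("dataset contains no arms")
        self.coding = coding
        label_pos = {lab: i for i, lab in enumerate(coding.labels)}

        for arm in arms:
            if arm.treatment not in label_pos:
                raise DataError(
                    f"arm treatment {arm.treatment!r} (study {arm.study!r}) "
                    f"not in treatment coding {coding.labels}"
                )

        # Group by study label (arms of a trial may be scattered in the input).
        studies: list[str] = []
        by_study: dict[str, list[ArmRecord]] = {}
        for arm in arms:
            if arm.study not in by_study:
                studies.append(arm.study)
                by_study[arm.study] = []
            by_study[arm.study].append(arm)

        for study, study_arms in by_study.items():
            seen = set()
            for arm in study_arms:
                if arm.treatment in seen:
                    raise DataError(
                        f"study {study!r} contains treatment {arm.treatment!r} twice"
                    )
                seen.add(arm.treatment)
            if len(study_arms) < 2:
                raise DataError(f"study {study!r} has fewer than 2 arms")

        ordered: list[ArmRecord] = []
        study_index: list[int] = []
        treatment_index: list[int] = []
        base: list[int] = []
        for j, study in enumerate(studies):
            study_arms = sorted(by_study[study], key=lambda a: label_pos[a.treatment])
            base.append(label_pos[study_arms[0].treatment])
            for arm in study_arms:
                ordered.append(arm)
                study_index.append(j)
                treatment_index.append(label_pos[arm.treatment])

        self.arms = tuple(ordered)
        self.studies = tuple(studies)
        self.study_index = np.asarray(study_index, dtype=np.int64)
        self.treatment_index = np.asarray(treatment_index, dtype=np.int64)
        self.trial_base_treatment = np.asarray(base, dtype=np.int64)
        self.events = np.asarray([a.events for a in ordered], dtype=np.int64)
        self.sizes = np.asarray([a.size for a in ordered], dtype=np.int64)

        self._check_connected()

    # ------------------------------------------------------------------ sizes
    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def n_trials(self) -> int:
        return len(self.studies)

    @property
    def n_treatments(self) -> int:
        return self.coding.n_treatments

    @property
    def arm_base_treatment(self) -> np.ndarray:
        """0-based base treatment ``b[i]`` of the trial each arm belongs to."""
        return self.trial_base_treatment[self.study_index]

    def trial_arms(self, j: int) -> np.ndarray:
        """Arm positions (canonical order) belonging to trial ``j`` (0-based)."""
        return np.flatnonzero(self.study_index == j)

    # ----------------------------------------------------------- construction
    @classmethod
    def from_arms(
        cls,
        arms: Iterable[ArmRecord],
        reference_treatment: str,
        treatment_order: Sequence[str] | None = None,
    ) -> "NmaDataset":
        """Build a dataset, assigning treatment indices.

        The reference treatment gets index 1; remaining treatments follow
        ``treatment_order`` if given, otherwise alphabetical order.
        """
        arms = tuple(arms)
        present = sorted({a.treatment for a in arms})
        if reference_treatment not in present:
            raise DataError(
                f"reference treatment {reference_treatment!r} not found; "
                f"treatments present: {present}"
            )
        if treatment_order is not None:
            order = [str(t) for t in treatment_order]
            if sorted(order) != present:
                raise DataError(
                    f"treatment_order {order} does not match treatments present {present}"
                )
            if order[0] != reference_treatment:
                raise DataError(
                    "treatment_order must start with the reference treatment"
                )
            labels = tuple(order)
        else:
            labels = (reference_treatment,) + tuple(
                t for t in present if t != reference_treatment
            )
        return cls(arms, TreatmentCoding(labels))

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        reference_treatment: str,
        treatment_order: Sequence[str] | None = None,
    ) -> "NmaDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(
                f"missing required column(s) {missing}; need {list(REQUIRED_COLUMNS)}"
            )
        arms = []
        for pos, row in enumerate(frame.itertuples(index=False)):
            try:
                arms.append(
                    ArmRecord(
                        study=str(getattr(row, "study")),
                        treatment=str(getattr(row, "treatment")),
                        events=getattr(row, "events"),
                        size=getattr(row, "size"),
                    )
                )
            except DataError as err:
                raise DataError(f"row {pos + 1}: {err}") from None
        return cls.from_arms(arms, reference_treatment, treatment_order)

    # ------------------------------------------------------------- operations
    def remove_studies(self, studies: Iterable[str]) -> "NmaDataset":
        """Return a new dataset without the named studies.

        Treatment indices are re-derived (a treatment left with no arms is
        dropped from the coding) and connectivity is re-checked.
        """
        drop = {str(s) for s in studies}
        unknown = drop - set(self.studies)
        if unknown:
            raise DataError(f"unknown study label(s): {sorted(unknown)}")
        kept = [a for a in self.arms if a.study not in drop]
        if not kept:
            raise DataError("removing these studies leaves no data")
        remaining = {a.treatment for a in kept}
        labels = tuple(t for t in self.coding.labels if t in remaining)
        if self.coding.reference not in remaining:
            raise DataError(
                "removing these studies removes every arm of the reference treatment"
            )
        return NmaDataset(kept, TreatmentCoding(labels))

    def network_summary(self) -> NetworkSummary:
        """Direct-comparison trial counts per pair plus per-treatment totals."""
        labels = self.coding.labels
        pair_trials: dict[tuple[str, str], int] = {
            (labels[a], labels[b]): 0
            for a in range(len(labels))
            for b in range(a + 1, len(labels))
        }
        for j in range(self.n_trials):
            treats = sorted(self.treatment_index[self.trial_arms(j)])
            for x in range(len(treats)):
                for y in range(x + 1, len(treats)):
                    pair_trials[(labels[treats[x]], labels[treats[y]])] += 1
        events = {lab: 0 for lab in labels}
        size = {lab: 0 for lab in labels}
        for arm in self.arms:
            events[arm.treatment] += arm.events
            size[arm.treatment] += arm.size
        return NetworkSummary(pair_trials, events, size)

    # ------------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study": [a.study for a in self.arms],
                "treatment": [a.treatment for a in self.arms],
                "events": self.events,
                "size": self.sizes,
            }
        )

    def write_long_table(self, path: str | Path) -> None:
        """Write the canonical long CSV (columns study,treatment,events,size)."""
        self.to_frame().to_csv(path, index=False)

    # ------------------------------------------------------------- internals
    def _check_connected(self) -> None:
        graph = nx.Graph()
        graph.add_nodes_from(range(self.n_treatments))
        for j in range(self.n_trials):
            treats = self.treatment_index[self.trial_arms(j)]
            for x in range(len(treats)):
                for y in range(x + 1, len(treats)):
                    graph.add_edge(int(treats[x]), int(treats[y]))
        if not nx.is_connected(graph):
            comps = [
                sorted(self.coding.labels[t] for t in comp)
                for comp in nx.connected_components(graph)
            ]
            raise DataError(
                f"treatment network is disconnected; components: {comps}"
            )

    # ------------------------------------------------------------ comparison
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NmaDataset):
            return NotImplemented
        return self.arms == other.arms and self.coding == other.coding

    def __repr__(self) -> str:
        return (
            f"NmaDataset(n_trials={self.n_trials}, n_arms={self.n_arms}, "
            f"n_treatments={self.n_treatments}, reference={self.coding.reference!r})"
        )


def load_long_table(
    path: str | Path,
    reference_treatment: str,
    treatment_order: Sequence[str] | None = None,
) -> NmaDataset:
    """Load a long-format CSV (columns ``study,treatment,events,size``).

    The reference treatment is assigned index 1; remaining treatments are
    indexed alphabetically unless ``treatment_order`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"data file not found: {path}")
    frame = pd.read_csv(path, dtype={"study": str, "treatment": str})
    return NmaDataset.from_frame(frame, reference_treatment, treatment_order)


def remove_studies(data: NmaDataset, studies: Iterable[str]) -> NmaDataset:
    """Functional alias for :meth:`NmaDataset.remove_studies`."""
    return data.remove_studies(studies)


def network_summary(data: NmaDataset) -> NetworkSummary:
    """Functional alias for :meth:`NmaDataset.network_summary`."""
    return data.network_summary()
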