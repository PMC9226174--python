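"""Patient-level "digital grade": majority vote over a patient's cell-graphs.

Each cell-graph of a patient is classified independently; the patient is
assigned the class holding the largest proportion of graph votes.  Ties
break toward the shorter-survival (lower-index) class — a deliberately
conservative triage convention, configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    proportions: tuple[float, ...]
    final_label: int
    n_graphs: int


def aggregate_patient(
    graph_labels,
    n_classes: int | None = None,
    patient_id: str = "",
    tie_break: str = "short",
) -> PatientPrediction:
    """Majority vote over one patient's predicted graph labels."""
    graph_labels = np.asarray(graph_labels, dtype=int)
    if len(graph_labels) == 0:
        raise ValueError(f"no graph predictions for patient {patient_id!r}")
    n_classes = n_classes or int(graph_labels.max()) + 1
    counts = np.bincount(graph_labels, minlength=n_classes).astype(float)
    props = counts / counts.sum()
    best = np.flatnonzero(counts == counts.max())
    final = int(best.min() if tie_break == "short" else best.max())
    return PatientPrediction(patient_id, tuple(props), final, len(graph_labels))


def aggregate_cohort(
    graph_pred_labels,
    graph_patient_ids,
    n_classes: int,
    tie_break: str = "short",
) -> pd.DataFrame:
    """One digital grade per patient from aligned per-graph predictions.

    Returns a DataFrame indexed by patient_id with the vote proportions,
    final label and graph count; includes patients whose graphs were
    inference-only (uncategorized for training).
    """
    graph_pred_labels = np.asarray(graph_pred_labels, dtype=int)
    if len(graph_pred_labels) != len(graph_patient_ids):
        raise ValueError("predictions and patient ids differ in length")
    by_patient: dict[str, list[int]] = {}
    for lab, pid in zip(graph_pred_labels, graph_patient_ids):
        by_patient.setdefault(str(pid), []).append(int(lab))
    rows = []
    for pid in sorted(by_patient):
        p = aggregate_patient(by_patient[pid], n_classes, pid, tie_break)
        rows.append(
            {"patient_id": pid, "final_label": p.final_label, "n_graphs": p.n_graphs,
             **{f"prop_class_{c}": p.proportions[c] for c in range(n_classes)}}
        )
    return pd.DataFrame(rows).set_index("patient_id")


def soft_aggregate_cohort(graph_probs, graph_patient_ids) -> pd.DataFrame:
    """Mean-probability (soft vote) variant of :func:`aggregate_cohort`."""
    graph_probs = np.asarray(graph_probs, dtype=float)
    df = pd.DataFrame(graph_probs)
    df["patient_id"] = [str(p) for p in graph_patient_ids]
    mean = df.groupby("patient_id").mean()
    out = pd.DataFrame(
        {"final_label": mean.to_numpy().argmax(axis=1),
         "n_graphs": df.groupby("patient_id").size()},
        index=mean.index,
    )
    for c in range(graph_probs.shape[1]):
        out[f"prop_class_{c}"] = mean[c]
    return out
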