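"""Rule-based binding-specificity classification.

Assigns a PH-domain sequence to one of four phosphoinositide
binding-specificity groups from its physicochemical profiles and a
motif scan, with a fixed rule order:

1. A 3-phosphate signature-motif hit overlapping the beta1/beta2 loop
   sends the sequence to the specific 3-phosphate binders {1, 3};
   otherwise to {2, 4}.
2. Within {1, 3}: a notable hydrophobic peak in the beta1/beta2 loop
   (max smoothed hydropathy >= tau_hydrophobic_peak) means Group 3,
   else Group 1 (whose loops are the most hydrophilic).
3. Within {2, 4}: a loop that is BOTH weakly charged (max smoothed
   electronic charge concentration < tau_charge) AND weakly
   hydrophilic (negated mean hydropathy < tau_hydrophilic) means the
   nonspecific Group 4, else Group 2.

Every prediction carries the evidence values and a structured rule
trace; replaying the trace reproduces the label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .motif import MotifHit
from .properties import SequenceProfile

REQUIRED_LOOP = "beta1_beta2"


@dataclass(frozen=True)
class LoopAnnotation:
    """Named loop windows as half-open position ranges.

    ``coordinate_system`` says whether ranges are residue indices of
    the ungapped sequence ("sequence") or alignment columns
    ("alignment"); the beta1/beta2 window is mandatory.
    """

    windows: Mapping[str, tuple[int, int]]
    coordinate_system: str = "sequence"

    def __post_init__(self):
        if REQUIRED_LOOP not in self.windows:
            raise ValueError(f"missing required loop window {REQUIRED_LOOP!r}")
        for name, (lo, hi) in self.windows.items():
            if not (0 <= lo < hi):
                raise ValueError(f"empty or invalid window {name!r}: {(lo, hi)}")
        object.__setattr__(self, "windows", dict(self.windows))

    def to_sequence(self, column_map: np.ndarray) -> "LoopAnnotation":
        """Convert alignment-column windows to sequence-index windows."""
        if self.coordinate_system == "sequence":
            return self
        out = {}
        for name, (lo, hi) in self.windows.items():
            inside = column_map[lo:hi]
            inside = inside[inside >= 0]
            if len(inside) == 0:
                continue
            out[name] = (int(inside.min()), int(inside.max()) + 1)
        return LoopAnnotation(windows=out, coordinate_system="sequence")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric thresholds operationalizing the qualitative rules.

    Defaults ship in ``data/classifier_config.yaml``; they were
    calibrated once on the synthetic archetype distributions (midpoint
    between group means; see ``scripts/calibrate_thresholds.py``).
    """

    tau_hydrophobic_peak: float
    tau_charge: float
    tau_hydrophilic: float

    def __post_init__(self):
        for name in ("tau_hydrophobic_peak", "tau_charge", "tau_hydrophilic"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def default_thresholds() -> ClassifierThresholds:
    cfg = yaml.safe_load(
        resources.files("phspec").joinpath(
            "data", "classifier_config.yaml").read_text()
    )
    return ClassifierThresholds(**cfg["thresholds"])


@dataclass
class GroupPrediction:
    """A group label with its evidence trail."""

    sequence_id: str
    group: int
    motif_hit: bool
    motif_location: tuple[int, int] | None
    loop_hydropathy_max: float
    loop_charge_max: float
    loop_hydrophilicity: float
    rule_trace: list[dict] = field(default_factory=list)


def classify(
    profiles: Mapping[str, SequenceProfile],
    motif_hits: list[MotifHit],
    loops: LoopAnnotation,
    thresholds: ClassifierThresholds | None = None,
) -> GroupPrediction:
    """Run the three-rule decision flow on one sequence.

    ``profiles`` must contain the hydropathy ("H") and electronic
    charge concentration ("E") scales; ``loops`` must be in sequence
    coordinates and include the beta1/beta2 window.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    for scale in ("H", "E"):
        if scale not in profiles:
            raise ValueError(f"missing required profile for scale {scale!r}")
    if loops.coordinate_system != "sequence":
        raise ValueError("loop windows must be in sequence coordinates")
    lo, hi = loops.windows[REQUIRED_LOOP]
    h = profiles["H"].values
    e = profiles["E"].values
    if hi > len(h):
        raise ValueError(
            f"beta1/beta2 window {(lo, hi)} exceeds sequence length {len(h)}"
        )
    seq_id = profiles["H"].sequence_id
    loop_h_max = float(np.max(h[lo:hi]))
    loop_e_max = float(np.max(e[lo:hi]))
    hydrophilicity = float(-np.mean(h[lo:hi]))

    in_loop = [m for m in motif_hits if m.in_loop]
    trace: list[dict] = [{
        "rule": "motif",
        "observed": bool(in_loop),
        "outcome": "{1,3}" if in_loop else "{2,4}",
    }]
    if in_loop:
        is_peak = loop_h_max >= thresholds.tau_hydrophobic_peak
        trace.append({
            "rule": "hydrophobic_peak",
            "observed": loop_h_max,
            "threshold": thresholds.tau_hydrophobic_peak,
            "comparison": ">=",
            "outcome": 3 if is_peak else 1,
        })
        group = 3 if is_peak else 1
    else:
        weak_charge = loop_e_max < thresholds.tau_charge
        weak_philic = hydrophilicity < thresholds.tau_hydrophilic
        trace.append({
            "rule": "weak_charge_and_hydrophilicity",
            "observed": (loop_e_max, hydrophilicity),
            "threshold": (thresholds.tau_charge, thresholds.tau_hydrophilic),
            "comparison": "< and <",
            "outcome": 4 if (weak_charge and weak_philic) else 2,
        })
        group = 4 if (weak_charge and weak_philic) else 2
    hit = in_loop[0] if in_loop else None
    return GroupPrediction(
        sequence_id=seq_id,
        group=group,
        motif_hit=bool(in_loop),
        motif_location=(hit.start, hit.end) if hit else None,
        loop_hydropathy_max=loop_h_max,
        loop_charge_max=loop_e_max,
        loop_hydrophilicity=hydrophilicity,
        rule_trace=trace,
    )


def replay_trace(prediction: GroupPrediction) -> int:
    """Re-execute a prediction's rule trace and return the group label."""
    first = prediction.rule_trace[0]
    assert first["rule"] == "motif"
    second = prediction.rule_trace[1]
    if first["observed"]:
        assert second["rule"] == "hydrophobic_peak"
        return 3 if second["observed"] >= second["threshold"] else 1
    assert second["rule"] == "weak_charge_and_hydrophilicity"
    (e_max, philic) = second["observed"]
    (tau_e, tau_p) = second["threshold"]
    return 4 if (e_max < tau_e and philic < tau_p) else 2


@dataclass
class EvaluationResult:
    """Confusion table of predicted vs reference groups."""

    confusion: pd.DataFrame  # rows: reference group, cols: predicted
    accuracy: float
    per_group_recall: dict[int, float]
    unmatched: list[str]


def evaluate_against_reference(
    predictions: Mapping[str, GroupPrediction],
    reference: Mapping[str, int],
) -> EvaluationResult:
    """Score predictions against reference group labels.

    Identifiers present on only one side are listed and excluded.
    """
    shared = sorted(set(predictions) & set(reference))
    unmatched = sorted(
        (set(predictions) | set(reference)) - set(shared)
    )
    if unmatched:
        warnings.warn(f"{len(unmatched)} unmatched identifiers excluded")
    groups = [1, 2, 3, 4]
    conf = pd.DataFrame(0, index=groups, columns=groups)
    for key in shared:
        conf.loc[reference[key], predictions[key].group] += 1
    total = conf.values.sum()
    accuracy = float(np.trace(conf.values) / total) if total else float("nan")
    recall = {}
    for g in groups:
        row = conf.loc[g].sum()
        recall[g] = float(conf.loc[g, g] / row) if row else float("nan")
    return EvaluationResult(
        confusion=conf,
        accuracy=accuracy,
        per_group_recall=recall,
        unmatched=unmatched,
    )
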