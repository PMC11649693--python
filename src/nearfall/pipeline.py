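"""End-to-end composition: calibrate, detect, classify, evaluate.

Also hosts the sensing-variant harness that re-runs the identical
pipeline with the angular acceleration replaced by a numerically
differenced gyroscope channel (the single-IMU baseline), used for
cluster-versus-IMU comparison studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence

from .classification import PerturbationCall, TaskReference, classify_trial
from .config import FrameworkConfig
from .errors import ConfigurationError
from .kinematics import KinematicsSeries, differentiate_omega
from .metrics import MetricsReport, evaluate
from .synthetic import BenchmarkSet, TrialLabel
from .thresholds import BaselineTrial, PersonalisedThresholds, calibrate

Method = Literal["imc", "central", "backward"]


def single_sensor_view(kin: KinematicsSeries, method: Method) -> KinematicsSeries:
    """The recording as a lone IMU would deliver it.

    ``imc`` returns the series unchanged; ``central``/``backward``
    replace the angular acceleration by the corresponding difference
    quotient of the (noisy) angular-velocity channel.
    """
    if method == "imc":
        return kin
    return differentiate_omega(kin, method)


@dataclass
class BenchmarkReport:
    """Evaluation of one pipeline variant over a benchmark corpus."""

    method: Method
    metrics: MetricsReport
    type_correct: int
    type_total: int
    preceding_correct: int
    preceding_total: int
    per_trial_calls: List[List[PerturbationCall]]
    thresholds: Dict[int, PersonalisedThresholds]

    @property
    def type_accuracy(self) -> Optional[float]:
        return self.type_correct / self.type_total if self.type_total else None

    @property
    def preceding_accuracy(self) -> Optional[float]:
        return (
            self.preceding_correct / self.preceding_total
            if self.preceding_total
            else None
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "metrics": self.metrics.to_dict(),
            "type_accuracy": self.type_accuracy,
            "preceding_accuracy": self.preceding_accuracy,
            "type_correct": self.type_correct,
            "type_total": self.type_total,
        }


def run_benchmark(
    benchmark: BenchmarkSet,
    config: Optional[FrameworkConfig] = None,
    method: Method = "imc",
) -> BenchmarkReport:
    """Calibrate per subject, classify every trial, score against labels.

    For difference-quotient methods the calibration baselines are
    transformed the same way as the trials, so the personalised
    thresholds reflect the noise amplification of the differenced
    signal, as they would in a real single-IMU deployment.
    """
    cfg = config or FrameworkConfig()
    thresholds: Dict[int, PersonalisedThresholds] = {}
    references: Dict[int, TaskReference] = {}
    for subject, trials in benchmark.baselines.items():
        transformed = [
            BaselineTrial(
                kin=single_sensor_view(b.kin, method),
                subject_id=b.subject_id,
                target_speed=b.target_speed,
                ground_truth=b.ground_truth,
            )
            for b in trials
        ]
        th = calibrate(transformed, cfg)
        thresholds[subject] = th
        references[subject] = TaskReference.from_thresholds(th, cfg)

    per_trial_calls: List[List[PerturbationCall]] = []
    for trial in benchmark.trials:
        kin = single_sensor_view(trial.kin, method)
        calls = classify_trial(kin, thresholds[trial.subject], references[trial.subject], cfg)
        per_trial_calls.append(calls)

    labels = benchmark.labels()
    report = evaluate(per_trial_calls, [lab.perturbed for lab in labels])

    type_correct = type_total = 0
    prec_correct = prec_total = 0
    for calls, lab in zip(per_trial_calls, labels):
        if not lab.perturbed:
            continue
        recoveries = [c for c in calls if c.is_recovery]
        if not recoveries:
            continue
        call = recoveries[0]
        type_total += 1
        if call.type == lab.type:
            type_correct += 1
        prec_total += 1
        if call.preceding == lab.preceding:
            prec_correct += 1

    return BenchmarkReport(
        method=method,
        metrics=report,
        type_correct=type_correct,
        type_total=type_total,
        preceding_correct=prec_correct,
        preceding_total=prec_total,
        per_trial_calls=per_trial_calls,
        thresholds=thresholds,
    )


def run_pipeline(
    config: FrameworkConfig,
    baselines: Sequence[BaselineTrial],
    trials: Sequence[KinematicsSeries],
    method: Method = "imc",
    labels: Optional[Sequence[bool]] = None,
) -> dict:
    """File-level pipeline: calibrate once, classify all trials, report.

    The result dict embeds the full configuration for provenance; when
    trial labels are supplied the metric report is included.
    """
    if not baselines:
        raise ConfigurationError("pipeline requires at least one baseline trial")
    th = calibrate(
        [
            BaselineTrial(
                kin=single_sensor_view(b.kin, method),
                subject_id=b.subject_id,
                target_speed=b.target_speed,
            )
            for b in baselines
        ],
        config,
    )
    refs = TaskReference.from_thresholds(th, config)
    per_trial = [
        classify_trial(single_sensor_view(kin, method), th, refs, config)
        for kin in trials
    ]
    result = {
        "config": config.to_dict(),
        "method": method,
        "thresholds": th.to_dict(),
        "trials": [[c.to_dict() for c in calls] for calls in per_trial],
    }
    if labels is not None:
        result["metrics"] = evaluate(per_trial, list(labels)).to_dict()
    return result
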