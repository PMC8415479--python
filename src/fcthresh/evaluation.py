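"""Comparison of thresholded functional matrices against structural truth.

Every ordered off-diagonal pair is classified by sign into three classes —
excitatory (+), no-connection (0), inhibitory (-) — in both the functional
output and the structural target, giving a 3x3 confusion matrix (rows =
target class, columns = output class).  Accuracy is the fraction of correctly
classified ordered pairs, i.e. the trace over the total N^2 - N; this is the
only denominator for which a perfect classifier scores exactly 1.

``run_benchmark`` drives the full pipeline (generate -> simulate -> estimate
-> threshold -> evaluate) over topologies, degree values, and methods.  The
density threshold is calibrated per realization to the link counts found by
the double-threshold run on the same connectivity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import topologies
from .fc_estimation import estimate_cm
from .graph_metrics import degree_sequences
from .simulator import SimulationConfig, run_network
from .thresholding import ddt, density_threshold, hard_threshold, shuffle_threshold

__all__ = ["EvaluationReport", "confusion_3class", "accuracy", "ei_ratio",
           "run_benchmark", "CLASSES"]

CLASSES = ("excitatory", "none", "inhibitory")


@dataclass
class EvaluationReport:
    confusion: np.ndarray  # 3x3, rows = target class, cols = output class
    accuracy: float
    n_links_detected: int
    ei_ratio_detected: float
    method_tag: str = ""
    network_id: str = ""
    extras: dict = field(default_factory=dict)


def _sign_class(matrix: np.ndarray) -> np.ndarray:
    """0 = excitatory, 1 = none, 2 = inhibitory."""
    return np.where(matrix > 0, 0, np.where(matrix < 0, 2, 1))


def confusion_3class(fm, truth) -> np.ndarray:
    """3x3 confusion counts over ordered off-diagonal pairs.

    ``fm`` may be a ThresholdResult or a matrix; ``truth`` a
    StructuralNetwork or a matrix.  Rows index the target (structural) class,
    columns the output (functional) class, in the order
    (excitatory, none, inhibitory).
    """
    fm_mat = fm.fm if hasattr(fm, "fm") else np.asarray(fm)
    tr_mat = truth.adjacency if hasattr(truth, "adjacency") else np.asarray(truth)
    if fm_mat.shape != tr_mat.shape:
        raise ValueError("functional and structural matrices differ in shape")
    n = fm_mat.shape[0]
    off = ~np.eye(n, dtype=bool)
    t = _sign_class(tr_mat)[off]
    o = _sign_class(fm_mat)[off]
    conf = np.zeros((3, 3), dtype=np.int64)
    np.add.at(conf, (t, o), 1)
    return conf


def accuracy(confusion: np.ndarray) -> float:
    """Fraction of correctly classified ordered pairs (trace / total)."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def ei_ratio(fm) -> float:
    """Fraction of detected links that are excitatory."""
    fm_mat = fm.fm if hasattr(fm, "fm") else np.asarray(fm)
    n_pos = int(np.count_nonzero(fm_mat > 0))
    n_neg = int(np.count_nonzero(fm_mat < 0))
    if n_pos + n_neg == 0:
        return float("nan")
    return n_pos / (n_pos + n_neg)


def noise_rate_for_degree(k: float, reference_degree: float = 40.0) -> float:
    """Noise-drive calibration for the degree sweep.

    The benchmark holds mean firing rates comparable across network
    configurations (sparser networks amplify the noise drive less), so the
    kick rate is raised for degrees below the reference: rate ~ (40/k)^2
    kicks/ms, floored at the reference 1 kick/ms.
    """
    return max(1.0, (reference_degree / float(k)) ** 2)


_GENERATORS = {
    "rnd": topologies.generate_random,
    "sw": topologies.generate_small_world,
    "sf": topologies.generate_scale_free,
    "modular": topologies.generate_modular,
}


def evaluate_threshold(result, net, method_tag=None, network_id="") -> EvaluationReport:
    """Confusion matrix, accuracy, link counts and E/I ratio of one result."""
    conf = confusion_3class(result, net)
    fm_mat = result.fm if hasattr(result, "fm") else np.asarray(result)
    deg = degree_sequences(fm_mat)
    return EvaluationReport(
        confusion=conf,
        accuracy=accuracy(conf),
        n_links_detected=int(np.count_nonzero(fm_mat)),
        ei_ratio_detected=ei_ratio(result),
        method_tag=method_tag or getattr(result, "method_tag", ""),
        network_id=network_id,
        extras={"in_degrees_exc": deg["in_excitatory"],
                "in_degrees_inh": deg["in_inhibitory"]},
    )


def run_benchmark(
    topology: str = "rnd",
    n_realizations: int = 1,
    k_values=(40,),
    methods=("DDT", "HT", "DT"),
    duration_s: float = 360.0,
    stdp_freeze_s: float = 60.0,
    estimation_from_s: float | None = None,
    n_neurons: int = 500,
    n_excitatory: int = 400,
    seed: int = 0,
    sh_shuffles: int = 20,
    ddt_params: dict | None = None,
    collect=None,
) -> pd.DataFrame:
    """Full-pipeline benchmark sweep.

    For each (realization, k, method): generate a structural network, simulate
    spontaneous activity, estimate the connectivity matrix from the
    post-plasticity window, threshold, and score against the ground truth.
    DT is calibrated to the DDT link counts of the same realization.  Failures
    of individual cells are recorded (accuracy NaN) and the sweep continues.

    ``collect``, if given, is called with ``(report, result, net, cm)`` for
    every cell, letting callers accumulate extra statistics (e.g. degree
    distributions) without re-running the pipeline.
    """
    topology = topology.lower()
    if topology not in _GENERATORS:
        raise ValueError(f"unknown topology {topology!r}")
    ddt_params = ddt_params or {}
    rows = []
    for rep in range(n_realizations):
        for k in k_values:
            net_seed = (seed * 1_000_003 + rep * 1009 + int(k)) % (2**31)
            try:
                if topology == "rnd":
                    net = topologies.generate_random(
                        n_neurons, n_excitatory, int(k), seed=net_seed)
                elif topology == "sw":
                    net = topologies.generate_small_world(
                        n_neurons, n_excitatory, int(k), seed=net_seed)
                elif topology == "sf":
                    net = topologies.generate_scale_free(
                        n_neurons, n_excitatory, min_links_per_neuron=max(1, int(k) // 2),
                        out_degree=int(k), seed=net_seed)
                else:
                    net = topologies.generate_modular(n_neurons, seed=net_seed)
                cfg = SimulationConfig(
                    duration_s=duration_s, stdp_freeze_s=stdp_freeze_s,
                    seed=net_seed + 7,
                    noise_rate=noise_rate_for_degree(k),
                )
                spikes = run_network(net, cfg)
                t0 = (estimation_from_s if estimation_from_s is not None
                      else stdp_freeze_s) * 1000.0
                rec = spikes.window(t0, spikes.duration_ms)
                cm = estimate_cm(rec)
            except Exception as exc:  # record the failed cell, keep sweeping
                warnings.warn(f"pipeline failure (rep={rep}, k={k}): {exc}")
                for method in methods:
                    rows.append({"topology": topology, "realization": rep,
                                 "k": k, "method": method, "accuracy": np.nan,
                                 "error": str(exc)})
                continue
            ddt_result = ddt(cm, **ddt_params)
            for method in methods:
                method = method.upper()
                if method == "DDT":
                    result = ddt_result
                elif method == "HT":
                    result = hard_threshold(cm)
                elif method == "DT":
                    result = density_threshold(
                        cm, ddt_result.n_exc_links, ddt_result.n_inh_links)
                elif method == "SH":
                    result = shuffle_threshold(
                        rec, cm, n_shuffles=sh_shuffles, seed=net_seed + 13)
                else:
                    raise ValueError(f"unknown method {method!r}")
                report = evaluate_threshold(
                    result, net, method, network_id=f"{topology}-k{k}-r{rep}")
                if collect is not None:
                    collect(report, result, net, cm)
                rows.append({
                    "topology": topology, "realization": rep, "k": k,
                    "method": method, "accuracy": report.accuracy,
                    "n_links": report.n_links_detected,
                    "ei_ratio": report.ei_ratio_detected,
                    "n_links_structural": net.n_links,
                    "seed": net_seed, "error": "",
                })
    return pd.DataFrame(rows)
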