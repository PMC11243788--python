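"""Experiment protocols: model comparison, channel ablation, transfer and
sequential (cyclic) learning, and multi-visit progressive adaptation.

Sequential learning is prequential: every stride is estimated and scored
*before* it enters the fine-tuning buffer, so the logged per-stride RMSE is
an honest out-of-sample figure.  After every `interval` strides the model
is warm-start fine-tuned on the strides seen so far (capped epochs or the
RMSE stopping rule, whichever first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .gait import GaitCycle, GaitCycleDataset
from .metrics import cc as _cc
from .metrics import convergence_rate, rmse as _rmse, snr as _snr
from .model import (GruAmConfig, KneeAngleGRU, KneeAngleGRUResults,
                    gru_baseline_config)
from .synthetic import SHARED6_CHANNELS

logger = logging.getLogger("emgknee")

__all__ = [
    "AblationReport", "SequentialRunLog", "compare_models", "ablate_channels",
    "pretrain_transfer", "personalize", "sequential_learn",
    "progressive_visits",
]

FINETUNE_EPOCHS = 50   # per-update budget; RMSE stopping rule still applies


@dataclass
class AblationReport:
    """Single-channel ablation results, ranked by RMSE increase."""

    full_rmse: float
    full_cc: float
    table: pd.DataFrame          # channel, rmse, cc, delta_rmse
    ranking: list[str]           # channels, largest delta_rmse first


@dataclass
class SequentialRunLog:
    """Per-stride prequential metrics of one sequential-learning run."""

    log: pd.DataFrame            # stride, rmse, cc, snr, cycle_index
    interval: int
    n_updates: int
    convergence_rate: float      # degrees per stride
    visit: str = "V1"

    def summary(self) -> dict:
        return {"visit": self.visit,
                "n_strides": len(self.log),
                "n_updates": self.n_updates,
                "mean_rmse": float(self.log["rmse"].mean()),
                "mean_cc": float(self.log["cc"].mean()),
                "mean_snr": float(self.log["snr"].mean()),
                "convergence_rate": self.convergence_rate}


def compare_models(dataset: GaitCycleDataset, cfg: GruAmConfig,
                   n_seeds: int = 5, max_epochs: int | None = None
                   ) -> pd.DataFrame:
    """Train GRU-AM and the attention-free GRU with matched seeds.

    Returns one row per (seed, variant) with test RMSE and CC; the two arms
    differ only in `use_attention`.
    """
    rows = []
    for k in range(n_seeds):
        for use_attention in (True, False):
            cfg_k = replace(cfg, seed=cfg.seed + k, use_attention=use_attention)
            res = KneeAngleGRU(dataset, cfg_k).fit(max_epochs=max_epochs)
            ev = res.evaluate(dataset.test_cycles)
            rows.append({"seed": cfg_k.seed,
                         "model": "GRU-AM" if use_attention else "GRU",
                         "test_rmse": float(ev["rmse"].mean()),
                         "test_cc": float(ev["cc"].mean()),
                         "epochs": res.n_epochs})
    return pd.DataFrame(rows)


def ablate_channels(dataset: GaitCycleDataset, cfg: GruAmConfig,
                    max_epochs: int | None = None) -> AblationReport:
    """Retrain with each channel removed (shared seed) and rank by delta RMSE."""
    channels = list(dataset.channels)
    if len(channels) < 2:
        raise ValueError("ablation needs at least 2 channels")
    full = KneeAngleGRU(dataset, cfg).fit(max_epochs=max_epochs)
    ev = full.evaluate(dataset.test_cycles)
    full_rmse = float(ev["rmse"].mean())
    full_cc = float(ev["cc"].mean())
    rows = []
    for ch in channels:
        reduced = dataset.drop_channel(ch)
        res = KneeAngleGRU(reduced, cfg).fit(max_epochs=max_epochs)
        ev = res.evaluate(reduced.test_cycles)
        r = float(ev["rmse"].mean())
        rows.append({"channel": ch, "rmse": r, "cc": float(ev["cc"].mean()),
                     "delta_rmse": r - full_rmse})
        logger.info("ablation %s: RMSE %.2f (delta %+.2f)", ch, r, r - full_rmse)
    table = pd.DataFrame(rows)
    ranking = list(table.sort_values("delta_rmse", ascending=False)["channel"])
    return AblationReport(full_rmse=full_rmse, full_cc=full_cc,
                          table=table, ranking=ranking)


def pretrain_transfer(source_dataset: GaitCycleDataset, cfg: GruAmConfig,
                      max_epochs: int | None = None) -> KneeAngleGRUResults:
    """Train on the 6-channel shared-muscle source set, tagging provenance."""
    if set(source_dataset.channels) != set(SHARED6_CHANNELS):
        raise ValueError(
            f"transfer pretraining requires the shared 6-channel set "
            f"{sorted(SHARED6_CHANNELS)}, got {sorted(source_dataset.channels)}")
    res = KneeAngleGRU(source_dataset, cfg).fit(max_epochs=max_epochs)
    res.meta["provenance"] = "open-source-pretrain"
    return res


def personalize(results: KneeAngleGRUResults, subject_cycles: list[GaitCycle],
                n_strides: int = 10,
                max_epochs: int | None = None) -> KneeAngleGRUResults:
    """Warm-start training on the first `n_strides` subject cycles."""
    if n_strides == 0:
        return results
    if n_strides > len(subject_cycles):
        raise ValueError(f"asked for {n_strides} strides, only "
                         f"{len(subject_cycles)} available")
    out = results.refit(subject_cycles[:n_strides], max_epochs=max_epochs)
    out.meta["personalized_strides"] = n_strides
    return out


def sequential_learn(results: KneeAngleGRUResults,
                     stream_cycles: list[GaitCycle], interval: int = 3,
                     finetune_epochs: int = FINETUNE_EPOCHS,
                     visit: str = "V1",
                     snr_mode: str = "literal"
                     ) -> tuple[SequentialRunLog, KneeAngleGRUResults]:
    """Prequential pass over a stride stream with cyclic fine-tuning.

    Each stride is estimated and logged before it is added to the buffer;
    after every `interval` strides the model is fine-tuned (warm start,
    `finetune_epochs` cap) on all strides seen so far.  Returns the log and
    the final model state (so visits can chain).
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if not stream_cycles:
        raise ValueError("empty stride stream")
    rows = []
    buffer: list[GaitCycle] = []
    n_updates = 0
    current = results
    for i, cyc in enumerate(stream_cycles):
        est = current.estimate_cycle(cyc)       # estimate BEFORE training on it
        rows.append({"stride": i, "rmse": _rmse(cyc.angle, est),
                     "cc": _cc(cyc.angle, est),
                     "snr": _snr(cyc.angle, est, mode=snr_mode),
                     "cycle_index": n_updates})
        buffer.append(cyc)
        if len(buffer) % interval == 0:
            current = current.refit(list(buffer), max_epochs=finetune_epochs)
            n_updates += 1
    log = pd.DataFrame(rows)
    assert n_updates == len(stream_cycles) // interval
    rate = convergence_rate(log["rmse"]) if len(log) >= 2 else float("nan")
    return (SequentialRunLog(log=log, interval=interval, n_updates=n_updates,
                             convergence_rate=rate, visit=visit), current)


def progressive_visits(results: KneeAngleGRUResults,
                       visits: list[list[GaitCycle]], interval: int = 3,
                       finetune_epochs: int = FINETUNE_EPOCHS
                       ) -> tuple[list[SequentialRunLog], KneeAngleGRUResults]:
    """Sequential learning across ordered visits; model state carries over."""
    if not visits:
        raise ValueError("need at least one visit")
    logs: list[SequentialRunLog] = []
    current = results
    for v, stream in enumerate(visits, start=1):
        run, current = sequential_learn(current, stream, interval=interval,
                                        finetune_epochs=finetune_epochs,
                                        visit=f"V{v}")
        logs.append(run)
    return logs, current
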