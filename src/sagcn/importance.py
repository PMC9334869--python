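"""ROI importance ranking from attention-pooling survival frequencies.

A trained SA-GCN scores every node at each pooling stage; nodes that the
attention repeatedly keeps on *test* graphs are, by construction, the ones
whose features the classifier found discriminative. The occurrence
probability of an ROI is the fraction of test graphs in which it survives the
designated pooling layer (the first, by default — deeper layers retain only
~k^L of the nodes and compress the ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TrainedModel, predict_proba


@dataclass
class ImportanceTable:
    rows: list[dict]  # (roi, probability), sorted by probability descending
    view: str
    layer: int
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.to_frame().head(n)


def collect_survivors(model: TrainedModel, test_pairs, view: str = "lo",
                      layer: int = 1) -> list[np.ndarray]:
    """Original-coordinate ROI indices surviving pooling layer ``layer`` per test graph."""
    if not model.config.pool:
        raise ValueError("model has no pooling layers (pool=False ablation)")
    if view not in model.config.branches:
        raise ValueError(f"view {view!r} not present in a {model.config.view!r} model")
    if not (1 <= layer <= model.config.blocks):
        raise ValueError(f"layer must lie in [1, {model.config.blocks}]")
    _, trace = predict_proba(model, test_pairs, collect_trace=True)
    return list(trace[view][layer - 1])


def occurrence_probability(survivor_sets: list[np.ndarray], r: int,
                           roi_names: list[str] | None = None,
                           view: str = "lo", layer: int = 1) -> ImportanceTable:
    """Per-ROI pooling-survival probability over a collection of test graphs.

    probability(roi) = (#graphs where roi survives) / (#graphs); the table is
    sorted descending, ties broken by ROI index for a stable order.
    """
    if not survivor_sets:
        raise ValueError("no survivor sets supplied")
    counts = np.zeros(r, dtype=float)
    for s in survivor_sets:
        idx = np.unique(np.asarray(s, dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= r):
            raise ValueError(f"survivor index out of range for R={r}")
        counts[idx] += 1.0
    probs = counts / len(survivor_sets)
    names = roi_names if roi_names is not None else [f"ROI{i:03d}" for i in range(r)]
    if len(names) != r:
        raise ValueError(f"{len(names)} ROI names for R={r}")
    order = np.lexsort((np.arange(r), -probs))
    rows = [{"roi": names[i], "roi_index": int(i), "probability": float(probs[i])}
            for i in order]
    return ImportanceTable(rows, view=view, layer=layer,
                           meta={"n_graphs": len(survivor_sets), "view": view, "layer": layer})
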