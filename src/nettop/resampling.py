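"""Class labeling and SMOTE oversampling.

The positive class (signature genes) is typically a few percent of the
vertices, so classifiers trained on the raw table collapse onto the
majority.  SMOTE rebalances by synthesizing minority rows on the segments
joining each minority point to one of its k nearest minority neighbors in
feature space, rather than duplicating rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .graph_io import GeneSet

logger = logging.getLogger("nettop")

__all__ = ["LabeledDataset", "label_dataset", "smote"]


@dataclass
class LabeledDataset:
    """Feature rows plus a binary signature label.

    ``frame`` holds one row per vertex (index = vertex id) with the feature
    columns, a ``label`` column (1 = signature gene) and a ``provenance``
    column ("original" or "synthetic").
    """

    frame: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("label", "provenance")]

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    @property
    def y(self) -> pd.Series:
        return self.frame["label"]

    @property
    def provenance(self) -> pd.Series:
        return self.frame["provenance"]

    @property
    def n_positive(self) -> int:
        return int(self.frame["label"].sum())

    @property
    def n_negative(self) -> int:
        return int((self.frame["label"] == 0).sum())

    def original(self) -> "LabeledDataset":
        return LabeledDataset(self.frame[self.frame["provenance"] == "original"])

    def __len__(self) -> int:
        return len(self.frame)


def label_dataset(table: pd.DataFrame, signature: GeneSet) -> LabeledDataset:
    """Attach binary labels: positive iff the vertex id is in the signature.

    Raises if no vertex matches (classification would be impossible); warns
    when every vertex matches.
    """
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ValueError("feature table contains non-finite values")
    labels = np.fromiter(
        (1 if v in signature else 0 for v in table.index), dtype=int, count=len(table)
    )
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError(
            "no signature gene matches a network vertex; check identifier namespaces"
        )
    if n_pos == len(table):
        logger.warning("every vertex is in the signature; labels are single-class")
    logger.info("matched %d of %d signature genes to vertices", n_pos, len(signature))
    frame = table.copy()
    frame["label"] = labels
    frame["provenance"] = "original"
    return LabeledDataset(frame)


def smote(
    data: LabeledDataset,
    k_neighbors: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> LabeledDataset:
    """Oversample the minority class up to exact balance with the majority.

    Each synthetic sample is x + u * (x_nn - x) for a minority row x, one of
    its ``k_neighbors`` nearest minority neighbors x_nn (Euclidean distance,
    unscaled features unless ``standardize``), and a single uniform
    u ~ U[0, 1) shared across features so the point stays on the segment.
    Original rows are preserved verbatim; output is deterministic given
    ``seed``.
    """
    frame = data.frame
    counts = frame["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present before oversampling")
    minority_label = counts.idxmin()
    n_min, n_maj = int(counts.min()), int(counts.max())
    if n_min == n_maj:
        return data
    if n_min < 2:
        raise ValueError("minority class needs at least 2 members for SMOTE")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n_min:
        logger.warning(
            "k_neighbors=%d >= minority size %d; clamping to %d",
            k_neighbors,
            n_min,
            n_min - 1,
        )
        k_neighbors = n_min - 1

    rng = np.random.default_rng(seed)
    feats = data.feature_names
    minority = frame[frame["label"] == minority_label]
    xm = minority[feats].to_numpy(dtype=float)
    if standardize:
        sd = xm.std(axis=0)
        sd[sd == 0] = 1.0
        xq = (xm - xm.mean(axis=0)) / sd
    else:
        xq = xm
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(xq)
    neighbor_idx = nn.kneighbors(xq, return_distance=False)[:, 1:]  # drop self

    needed = n_maj - n_min
    per_row = np.full(n_min, needed // n_min)
    per_row[rng.choice(n_min, size=needed % n_min, replace=False)] += 1

    rows = []
    for i in range(n_min):
        for _ in range(per_row[i]):
            j = neighbor_idx[i, rng.integers(k_neighbors)]
            u = rng.random()
            rows.append(xm[i] + u * (xm[j] - xm[i]))
    synth = pd.DataFrame(
        rows,
        columns=feats,
        index=pd.Index([f"synthetic{t:05d}" for t in range(needed)], name=frame.index.name),
    )
    synth["label"] = minority_label
    synth["provenance"] = "synthetic"
    return LabeledDataset(pd.concat([frame, synth]))
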