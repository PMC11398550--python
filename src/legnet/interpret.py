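"""Subgraph-level interpretation of trained models.

Each subject's forward pass yields an N × k matrix of node-to-subgraph
assignment scores.  Averaging these across a cohort and ranking subgraphs by
their mean total score identifies the subgraphs the model leans on; each ROI
is assigned to the subgraph with its highest mean score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ToyAtlas
from .errors import ContractError


@dataclass
class SubgraphAssignment:
    """Cohort-averaged assignment scores and derived memberships.

    ``membership`` holds 1-based subgraph ids (argmax of the mean score per
    ROI; ties go to the lowest id).  ``subgraph_rank`` lists subgraph ids in
    descending order of mean score.
    """

    mean_scores: np.ndarray  # N x k
    membership: np.ndarray   # length N, values in 1..k
    subgraph_rank: np.ndarray  # length k, 1-based ids

    @property
    def n_rois(self):
        return self.mean_scores.shape[0]

    @property
    def k(self):
        return self.mean_scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean_scores,
                          columns=[f"subgraph_{j + 1}" for j in range(self.k)])
        df.insert(0, "roi", np.arange(1, self.n_rois + 1))
        df["membership"] = self.membership
        return df


def average_scores(score_matrices) -> SubgraphAssignment:
    """Element-wise mean of per-subject N × k score matrices."""
    stack = np.asarray(score_matrices, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ContractError("need a nonempty stack of N x k score matrices")
    mean = stack.mean(axis=0)
    membership = mean.argmax(axis=1) + 1  # argmax takes the lowest index on ties
    rank = np.argsort(-mean.mean(axis=0), kind="stable") + 1
    return SubgraphAssignment(mean_scores=mean, membership=membership,
                              subgraph_rank=rank)


def top_subgraphs(assignment: SubgraphAssignment, m: int):
    """The m highest-ranked subgraphs with their member ROI ids (1-based)."""
    if not (1 <= m <= assignment.k):
        raise ContractError(f"m must be in 1..{assignment.k}")
    out = []
    for sid in assignment.subgraph_rank[:m]:
        members = np.flatnonzero(assignment.membership == sid) + 1
        out.append((int(sid), members.tolist()))
    return out


def membership_volume(assignment: SubgraphAssignment, atlas: ToyAtlas) -> np.ndarray:
    """Project ROI memberships back onto the atlas grid (0 = background)."""
    if assignment.n_rois != atlas.n_rois:
        raise ContractError("assignment and atlas disagree on N")
    lut = np.concatenate([[0], assignment.membership.astype(np.int32)])
    vol = np.zeros(atlas.grid_shape, dtype=np.int32)
    vol[atlas.gm_mask] = lut[atlas.label_volume[atlas.gm_mask]]
    return vol


def export_assignment(assignment: SubgraphAssignment, csv_path, json_path,
                      m: int = 2) -> None:
    """Write the per-ROI score table (CSV) and a top-m summary (JSON)."""
    assignment.to_frame().to_csv(csv_path, index=False)
    summary = {
        "subgraph_rank": assignment.subgraph_rank.tolist(),
        "top_subgraphs": [
            {"subgraph": sid, "rois": members}
            for sid, members in top_subgraphs(assignment, m)
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
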