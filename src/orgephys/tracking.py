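"""Multi-day tracking of single units by electrical-footprint matching.

With a fixed electrode configuration across sessions, the same neuron leaves a
near-identical footprint each day. Units of consecutive days are matched by
the one-to-one assignment that maximizes total cosine similarity between
flattened footprints on the shared channels; matches below the similarity
threshold are rejected. Chains of matches define units tracked across spans
(day 1->2, 1->3, 1->4, ...); the tracked count is non-increasing with span by
construction. Cosine similarity makes the match invariant to global gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["TrackingResult", "match_sessions", "cosine_similarity_matrix"]


def cosine_similarity_matrix(efs_a, efs_b) -> np.ndarray:
    """Pairwise cosine similarity of flattened footprints (rows: a, cols: b)."""
    shape = efs_a[0].waveform.shape
    for ef in list(efs_a) + list(efs_b):
        if ef.waveform.shape != shape:
            raise ValueError(
                "all footprints must share the electrode configuration "
                f"(shape {shape} vs {ef.waveform.shape})"
            )
    A = np.vstack([np.asarray(ef.waveform, dtype=float).ravel() for ef in efs_a])
    B = np.vstack([np.asarray(ef.waveform, dtype=float).ravel() for ef in efs_b])
    A = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-30)
    B = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-30)
    return A @ B.T


@dataclass
class TrackingResult:
    """Matches per consecutive day pair plus per-span tracked counts.

    ``matches`` holds (day_a, day_b, unit_a, unit_b, similarity) records for
    consecutive-day assignments; ``tracked_counts[k]`` is the number of day-1
    units whose match chain extends unbroken to day k+1.
    """

    matches: list = field(default_factory=list)
    tracked_counts: dict = field(default_factory=dict)
    chains: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matches, columns=["day_a", "day_b", "unit_a", "unit_b", "similarity"]
        )


def match_sessions(efs_by_day, sim_threshold: float = 0.85) -> TrackingResult:
    """Track units across daily sessions on a fixed electrode configuration.

    ``efs_by_day`` is a sequence of footprint lists, one per day. For each
    consecutive day pair the optimal one-to-one assignment under total cosine
    similarity is computed (Hungarian algorithm) and matches with similarity
    >= ``sim_threshold`` accepted. A day-1 unit counts as tracked to day k when
    every consecutive link of its chain holds.
    """
    efs_by_day = [list(day) for day in efs_by_day]
    if len(efs_by_day) < 2:
        raise ValueError("need at least two sessions")
    result = TrackingResult()
    links = []  # per day pair: dict unit_a -> (unit_b, sim)
    for d in range(len(efs_by_day) - 1):
        a, b = efs_by_day[d], efs_by_day[d + 1]
        link: dict[int, tuple[int, float]] = {}
        if a and b:
            sim = cosine_similarity_matrix(a, b)
            rows, cols = linear_sum_assignment(-sim)
            for i, j in zip(rows, cols):
                s = float(sim[i, j])
                if s >= sim_threshold:
                    ua, ub = int(a[i].unit_id), int(b[j].unit_id)
                    link[ua] = (ub, s)
                    result.matches.append((d + 1, d + 2, ua, ub, s))
        links.append(link)
    # follow chains from day 1
    for ef in efs_by_day[0]:
        chain = [int(ef.unit_id)]
        for link in links:
            if chain[-1] not in link:
                break
            chain.append(link[chain[-1]][0])
        result.chains.append(chain)
    for span in range(2, len(efs_by_day) + 1):
        result.tracked_counts[f"1->{span}"] = sum(
            1 for c in result.chains if len(c) >= span
        )
    return result
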