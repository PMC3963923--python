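"""Local-ancestry bookkeeping.

Diploid local ancestry is the count (0/1/2) of African-origin alleles an
individual carries at a marker.  Upstream sliding-window estimators emit
per-window calls and leave two gaps this module fills with the standard
post-hoc rules: markers covered by several overlapping windows are resolved
by majority vote, and markers never genotyped on the array take the ancestry
of the nearest genotyped marker.  Global ancestry theta is the genome-wide
mean of the diploid counts divided by two.

Coordinates are 1-based and intervals closed, following VCF convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROVENANCE = ("direct", "window-vote", "nearest-marker")


@dataclass
class LocalAncestryTrack:
    """African-allele counts per individual x marker, with call provenance."""

    markers: pd.DataFrame                 #: marker_id, chrom, pos
    counts: np.ndarray                    #: (n, M) values in {0, 1, 2}
    provenance: np.ndarray | None = None  #: per-marker label from PROVENANCE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.markers):
            raise ValueError("counts must be (n_individuals, n_markers)")
        if self.counts.size and not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("ancestry counts must be in {0, 1, 2}")
        if self.provenance is None:
            self.provenance = np.full(len(self.markers), "direct", dtype=object)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.provenance.shape[0] != len(self.markers):
            raise ValueError("one provenance label per marker required")
        bad = set(self.provenance) - set(PROVENANCE)
        if bad:
            raise ValueError(f"unknown provenance labels: {sorted(bad)}")


def majority_vote_impute(window_calls) -> int:
    """Resolve one marker's ancestry from the calls of overlapping windows.

    Returns the modal count; ties are broken deterministically in favour of
    the smallest count.
    """
    calls = np.asarray(window_calls)
    if calls.size == 0:
        raise ValueError("majority vote needs at least one window call")
    if not np.isin(calls, (0, 1, 2)).all():
        raise ValueError("window calls must be ancestry counts in {0, 1, 2}")
    votes = np.bincount(calls.astype(int), minlength=3)
    return int(np.argmax(votes))  # argmax returns the first (lowest) maximiser


def nearest_marker_assign(typed_positions, typed_ancestry, query_positions) -> np.ndarray:
    """Assign each query position the ancestry of the closest typed marker.

    ``typed_ancestry`` may be 1-d (one individual) or (n, M); equidistant
    ties go to the lower position.
    """
    pos = np.asarray(typed_positions, dtype=float)
    anc = np.asarray(typed_ancestry)
    q = np.atleast_1d(np.asarray(query_positions, dtype=float))
    if pos.size == 0:
        raise ValueError("no typed markers to assign from")
    if np.any(np.diff(pos) < 0):
        raise ValueError("typed positions must be sorted")
    if anc.shape[-1] != pos.size:
        raise ValueError("typed_ancestry last axis must match typed_positions")
    # index of nearest typed marker, left neighbour winning exact ties
    right = np.searchsorted(pos, q, side="left")
    right = np.clip(right, 0, pos.size - 1)
    left = np.clip(right - 1, 0, pos.size - 1)
    use_left = np.abs(q - pos[left]) <= np.abs(pos[right] - q)
    idx = np.where(use_left, left, right)
    return anc[..., idx]


def global_ancestry(track: LocalAncestryTrack | np.ndarray) -> np.ndarray:
    """Per-individual global African ancestry: mean over markers of count/2."""
    counts = track.counts if isinstance(track, LocalAncestryTrack) else np.asarray(track)
    if counts.ndim != 2 or counts.shape[1] < 1:
        raise ValueError("need a (n_individuals, n_markers) matrix with >= 1 marker")
    counts = counts.astype(float)
    if np.isnan(counts).all(axis=1).any():
        raise ValueError("individual with no ancestry calls")
    return np.nanmean(counts, axis=1) / 2.0
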