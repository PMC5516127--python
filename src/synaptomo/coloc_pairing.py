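"""Tau colocalization classification and synaptic-pair detection.

Two questions drive this module.  First, which postsynapses contain human
tau?  A postsynaptic punctum is classified tau-positive when at least 50%
of its voxels fall inside the tau-channel foreground — the overlap is a
fraction of the *target* punctum's volume, because the question is which
synapse objects contain tau.  Second, which presynapse/postsynapse pairs
form putative synapses?  A GFP-positive presynapse and a postsynapse whose
centroids lie within 0.5 μm (in physical units, z anisotropic) are treated
as one putative synaptic pair; matching is one-to-one, greedy by ascending
distance, so each compartment belongs to at most one synapse.

Percentages are pooled per mouse by summing counts across image crops
(sum of positives / sum of totals), never by averaging crop percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import GridMismatchError
from .puncta3d import Punctum, PunctaCollection, overlap_fraction
from .segmentation import BinaryMask

DEFAULT_MIN_OVERLAP = 0.5
DEFAULT_MAX_PAIR_DIST_UM = 0.5
_REL_TOL = 1e-9  # float slack on the inclusive distance boundary


@dataclass(frozen=True)
class ColocalizationRecord:
    """Overlap classification for one target punctum."""

    punctum_id: int
    overlap_fraction: float
    positive: bool


@dataclass(frozen=True)
class SynapticPair:
    """A matched presynapse/postsynapse within the pairing distance."""

    pre_id: int
    post_id: int
    distance_um: float


def classify_overlap(
    targets: PunctaCollection,
    reference_mask: BinaryMask,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> list[ColocalizationRecord]:
    """Classify each target punctum against a reference foreground.

    ``positive`` ⇔ overlap fraction ≥ ``min_overlap`` (inclusive).
    """
    records = []
    for p in targets:
        if p.voxels.size and (p.voxels.max(axis=0) >= reference_mask.data.shape).any():
            raise GridMismatchError(
                f"punctum {p.id} voxels fall outside the reference mask grid "
                f"{reference_mask.data.shape}"
            )
        frac = overlap_fraction(p, reference_mask)
        records.append(ColocalizationRecord(p.id, frac, frac >= min_overlap))
    return records


def percent_positive(records: Iterable[ColocalizationRecord]) -> float | None:
    """100 × positives / total over pooled records; None when empty."""
    records = list(records)
    if not records:
        return None
    return 100.0 * sum(r.positive for r in records) / len(records)


def percent_post_tau(records: Iterable[ColocalizationRecord]) -> float | None:
    """Percentage of postsynapses colocalizing with tau (sum-pooled).

    Callers pool by concatenating the per-crop record lists; the ratio of
    summed counts then implements the per-mouse pooling rule.
    """
    return percent_positive(records)


def _distance(a: Punctum, b: Punctum) -> float:
    ax, ay, az = a.centroid_um
    bx, by, bz = b.centroid_um
    return math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)


def find_pairs(
    pre: PunctaCollection,
    post: PunctaCollection,
    max_pair_dist_um: float = DEFAULT_MAX_PAIR_DIST_UM,
    one_to_one: bool = True,
) -> list[SynapticPair]:
    """Match presynapses to postsynapses within a centroid distance.

    Candidates are all (pre, post) with Euclidean centroid distance ≤
    ``max_pair_dist_um`` (inclusive, with a tiny relative tolerance for
    float rounding).  With ``one_to_one`` (default) candidates are matched
    greedily by ascending distance, ties broken by (pre id, post id); each
    punctum then appears in at most one pair.  With ``one_to_one=False``
    every candidate is returned (sensitivity-analysis mode).
    """
    cutoff = max_pair_dist_um * (1.0 + _REL_TOL) + _REL_TOL * 1e-3
    candidates = []
    for p in pre:
        for q in post:
            d = _distance(p, q)
            if d <= cutoff:
                candidates.append((d, p.id, q.id))
    candidates.sort()
    if not one_to_one:
        return [SynapticPair(pid, qid, d) for d, pid, qid in candidates]
    used_pre: set[int] = set()
    used_post: set[int] = set()
    pairs = []
    for d, pid, qid in candidates:
        if pid in used_pre or qid in used_post:
            continue
        used_pre.add(pid)
        used_post.add(qid)
        pairs.append(SynapticPair(pid, qid, d))
    return pairs


def percent_pairs_tau(
    pairs: Sequence[SynapticPair],
    pre_records: Iterable[ColocalizationRecord],
    post_records: Iterable[ColocalizationRecord],
) -> float | None:
    """Percentage of synaptic pairs in which BOTH compartments are tau-positive.

    ``pre_records`` / ``post_records`` come from :func:`classify_overlap`
    run against the tau mask for each side.  Returns None with zero pairs.
    """
    pairs = list(pairs)
    if not pairs:
        return None
    pre_pos = {r.punctum_id: r.positive for r in pre_records}
    post_pos = {r.punctum_id: r.positive for r in post_records}
    both = sum(
        pre_pos.get(p.pre_id, False) and post_pos.get(p.post_id, False) for p in pairs
    )
    return 100.0 * both / len(pairs)
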