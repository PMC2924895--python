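"""Indel-driven Type I / Type II error analysis for the OFR threshold.

The threshold t is derived from the dataset's average length a.  Sequences
shorter than a (deletions) are judged against a threshold that is too weak,
risking false positive resolution (Type I); sequences longer than a
(insertions) face a too-stringent threshold, risking false negatives
(Type II).  Two diagnostics are provided:

* the minimum indel length m whose worst-case single-oligo frequency
  perturbation Δ(L) = (L + k − 1) / (a − L − k + 1) reaches the decision
  margin of a pair (an indel of length L touches at most L+k−1 windows and
  shifts the window count by L) — Δ is a conservative reconstruction of the
  worst case, isolated here so it can be swapped out;
* the length-asymmetry rule: with D_l the excess of the longest sequence
  over a and D_s the shortfall of the shortest, D_s > D_l flags Type I and
  D_l > D_s flags Type II.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AuditError, ConfigError
from .ofr_core import ResolutionMatrix, ThresholdSpec
from .seqdata import BarcodeDataset


@dataclass
class IndelRiskReport:
    """Per-pair indel risk: minimal risky indel length and the length rule."""

    species_a: str
    species_b: str
    m: int | None  # None = no finite indel length reaches the margin
    x: float  # signed extreme gap (negative = overlap)
    error_type: str  # "type_I" | "type_II" | "none"
    D_l: int
    D_s: int


def perturbation_bound(L: int, a: float, k: int) -> float:
    """Worst-case single-oligo frequency shift from an indel of length L."""
    denom = a - L - k + 1
    if denom <= 0:
        return math.inf
    return (L + k - 1) / denom


def min_indel_for_error(
    ts: ThresholdSpec, x: float, direction: str
) -> int | None:
    """Smallest indel length m whose worst-case perturbation flips a pair.

    ``x`` is the pair's signed extreme separation (gap if positive, overlap
    magnitude as a negative value).  For deletions the margin is |x| + t
    (enough to fake a gap of t across the largest overlap, Type I); for
    insertions it is x − t (enough to push the best gap below t, Type II) —
    a non-positive insertion margin means any insertion threatens the pair
    (m = 1).  Returns ``None`` when no indel short enough to keep
    a − L − k + 1 positive reaches the margin.
    """
    if direction == "deletion":
        margin = abs(x) + ts.t
    elif direction == "insertion":
        margin = x - ts.t
        if margin <= 0:
            return 1
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    a, k = ts.average_length, ts.k
    L = 1
    while a - L - k + 1 > 0:
        if perturbation_bound(L, a, k) >= margin - 1e-12:
            return L
        L += 1
    return None


def pair_length_risk(D_l: int, D_s: int) -> str:
    """Length-asymmetry error rule: D_s > D_l → Type I, D_l > D_s → Type II."""
    if D_l < 0 or D_s < 0:
        raise ConfigError("D_l and D_s must be non-negative")
    if D_s > D_l:
        return "type_I"
    if D_l > D_s:
        return "type_II"
    return "none"


def dataset_indel_audit(
    ds: BarcodeDataset, rm: ResolutionMatrix, ts: ThresholdSpec
) -> list[IndelRiskReport]:
    """Apply both indel-risk rules to every evaluated species pair.

    ``D_l``/``D_s`` are measured from the pair's longest/shortest ungapped
    record lengths against the dataset average; ``x`` comes from the pair's
    resolution evidence.  Pairs whose ``error_type`` is not ``"none"`` are
    the flagged ones.
    """
    lengths = {
        sp: [r.source_length for r in recs]
        for sp, recs in ds.species_index.items()
    }
    for sp, ls in lengths.items():
        if len(set(ls)) > 1:
            warnings.warn(
                f"species {sp} has unequal accession lengths; the minimal-"
                "indel diagnostic assumes equal lengths within a species",
                stacklevel=2,
            )
    a = ds.average_length
    reports: list[IndelRiskReport] = []
    for key, pr in rm.evidence.items():
        if pr.status == "not_evaluable":
            continue
        if math.isnan(pr.max_gap):
            raise AuditError(f"pair {sorted(key)} lacks gap evidence")
        sa, sb = pr.species_a, pr.species_b
        pair_lengths = lengths[sa] + lengths[sb]
        D_l = max(0, int(round(max(pair_lengths) - a)))
        D_s = max(0, int(round(a - min(pair_lengths))))
        err = pair_length_risk(D_l, D_s)
        if err == "type_I":
            direction = "deletion"
        elif err == "type_II":
            direction = "insertion"
        else:
            # no length asymmetry: the live threat is the flip of the pair's
            # current status (resolved -> insertion, unresolved -> deletion)
            direction = "insertion" if pr.resolved else "deletion"
        m = min_indel_for_error(ts, pr.max_gap, direction)
        reports.append(
            IndelRiskReport(
                species_a=sa,
                species_b=sb,
                m=m,
                x=pr.max_gap,
                error_type=err,
                D_l=D_l,
                D_s=D_s,
            )
        )
    return reports
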