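"""Seeded synthetic multi-species barcode datasets.

The generator mirrors the hierarchical structure of curated barcode
projects: a uniform-random root sequence, one ancestor per species, and
several accessions per species.  Substitutions are Jukes–Cantor-like
(uniform over the three alternative bases, independent sites).  Rates are
parameterised so that the expected divergence of an accession from the root
equals ``inter_div`` and the expected accession-to-species-ancestor
divergence equals ``intra_div``: the species-ancestor step therefore mutates
at per-site probability ``inter_div − intra_div``.  Setting
``inter_div == intra_div`` collapses the species layer entirely — every
accession is an independent draw around the root, a structureless null in
which species labels are arbitrary.

Optional per-site indels and region masks (variable sites confined to a
sub-interval, e.g. to build mini-barcode fixtures) are supported.  The same
seed always reproduces the same dataset.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .seqdata import BarcodeDataset, SequenceRecord

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimSpec:
    """Conditions for one synthetic dataset.

    ``inter_div`` is the expected per-site divergence of any accession from
    the root (so cross-species pairs diverge by roughly twice this value);
    it may be a single rate or one rate per species for graded divergence.
    ``intra_div`` is the expected accession-to-species-ancestor divergence.
    ``inter_region``/``intra_region`` confine the respective substitutions
    to a half-open interval of sites (None = whole locus).
    """

    n_species: int = 10
    accessions_per_species: int = 5
    locus_length: int = 600
    inter_div: float | Sequence[float] = 0.05
    intra_div: float = 0.005
    indel_rate: float = 0.0
    indel_len_mean: float = 3.0
    seed: int = 0
    inter_region: tuple[int, int] | None = None
    intra_region: tuple[int, int] | None = None

    @property
    def inter_divs(self) -> list[float]:
        if np.isscalar(self.inter_div):
            return [float(self.inter_div)] * self.n_species
        return [float(v) for v in self.inter_div]

    def validate(self) -> None:
        if self.n_species < 1 or self.accessions_per_species < 1:
            raise ValidationError("species and accession counts must be >= 1")
        if self.locus_length < 50:
            raise ValidationError("locus_length must be >= 50")
        divs = self.inter_divs
        if len(divs) != self.n_species:
            raise ValidationError("need one inter_div per species")
        for d in divs:
            if not 0.0 <= self.intra_div <= d <= 0.75:
                raise ValidationError(
                    "require 0 <= intra_div <= inter_div <= 0.75"
                )
        if self.indel_rate < 0 or self.indel_len_mean < 1:
            raise ValidationError("invalid indel parameters")
        for region in (self.inter_region, self.intra_region):
            if region is not None:
                lo, hi = region
                if not 0 <= lo < hi <= self.locus_length:
                    raise ValidationError(f"region {region} outside the locus")


def expected_pairwise_divergence(q1: float, q2: float) -> float:
    """Expected p-distance between two sequences independently mutated from
    a common ancestor at per-site substitution probabilities q1 and q2
    (each substitution uniform over the three alternative bases)."""
    same = (1 - q1) * (1 - q2) + q1 * q2 / 3
    return 1 - same


def _mask(region: tuple[int, int] | None, length: int) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    if region is None:
        m[:] = True
    else:
        m[region[0] : region[1]] = True
    return m


def _substitute(
    rng: np.random.Generator, seq: np.ndarray, rate: float, mask: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    hit = (rng.random(seq.size) < rate) & mask
    out = seq.copy()
    positions = np.nonzero(hit)[0]
    for pos in positions:
        choices = _ACGT[_ACGT != out[pos]]
        out[pos] = rng.choice(choices)
    return out, positions.tolist()


def _apply_indels(
    rng: np.random.Generator,
    seq: np.ndarray,
    rate: float,
    len_mean: float,
) -> tuple[np.ndarray, list[dict]]:
    if rate <= 0:
        return seq, []
    events: list[dict] = []
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    out = seq
    offset = 0
    for pos in hit:
        length = int(rng.geometric(1.0 / len_mean))
        p = pos + offset
        if rng.random() < 0.5 and p + length <= out.size:
            out = np.delete(out, slice(p, p + length))
            offset -= length
            events.append({"kind": "deletion", "pos": int(pos), "len": length})
        else:
            ins = rng.choice(_ACGT, size=length)
            out = np.insert(out, p, ins)
            offset += length
            events.append({"kind": "insertion", "pos": int(pos), "len": length})
    return out, events


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def generate_dataset(spec: SimSpec) -> tuple[BarcodeDataset, dict]:
    """Draw a dataset under ``spec``; returns (dataset, truth record).

    The truth record holds the root, each species ancestor, and every
    substitution position and indel event, enough to replay the history.
    Deterministic under a fixed seed.  The dataset is flagged aligned when
    no indels were drawn (all records share the root's coordinates).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.locus_length
    root = rng.choice(_ACGT, size=L)
    inter_mask = _mask(spec.inter_region, L)
    intra_mask = _mask(spec.intra_region, L)
    records: list[SequenceRecord] = []
    truth: dict = {
        "spec": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in asdict(spec).items()
        },
        "root": _to_str(root),
        "species": {},
    }
    any_indel = False
    for i, anc_rate in enumerate(spec.inter_divs):
        sp = f"Sp{i + 1:03d}"
        ancestor, anc_pos = _substitute(
            rng, root, anc_rate - spec.intra_div, inter_mask
        )
        sp_truth = {
            "ancestor": _to_str(ancestor),
            "ancestor_substitutions": anc_pos,
            "accessions": {},
        }
        for j in range(spec.accessions_per_species):
            acc = f"a{j + 1}"
            seq, sub_pos = _substitute(rng, ancestor, spec.intra_div, intra_mask)
            seq, indels = _apply_indels(
                rng, seq, spec.indel_rate, spec.indel_len_mean
            )
            any_indel = any_indel or bool(indels)
            records.append(SequenceRecord(sp, acc, _to_str(seq)))
            sp_truth["accessions"][acc] = {
                "substitutions": sub_pos,
                "indels": indels,
            }
        truth["species"][sp] = sp_truth
    ds = BarcodeDataset(records, aligned=not any_indel)
    return ds, truth
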