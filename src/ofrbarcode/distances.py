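"""Distance-based species resolution criteria.

Two metrics: the uncorrected p-distance on aligned sequences (pairwise
deletion of gapped/ambiguous sites) and the Euclidean distance between
oligonucleotide frequency profiles.  A species passes the barcoding-gap
criterion when its minimum interspecific distance strictly exceeds its
maximum intraspecific distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigError,
    UndefinedDistanceError,
    UndefinedScoreError,
)
from .oligofreq import KmerProfile, kmer_frequencies
from .seqdata import BarcodeDataset

_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    # non-ACGT (gaps, ambiguity codes) -> 255, excluded pairwise
    out = np.full(len(seq), 255, dtype=np.uint8)
    for c, i in _CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(c)] = i
    return out


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-comparable sites."""
    if len(a) != len(b):
        raise AlignmentError("p-distance requires equal gapped lengths")
    ea, eb = _encode(a), _encode(b)
    valid = (ea != 255) & (eb != 255)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites")
    return float(((ea != eb) & valid).sum()) / n


def euclidean_distance(p1: KmerProfile, p2: KmerProfile) -> float:
    """sqrt of the summed squared frequency differences over all 4^k oligos."""
    if p1.k != p2.k:
        raise ConfigError(f"mismatched k: {p1.k} vs {p2.k}")
    d = p1.vector - p2.vector
    return float(np.sqrt(d @ d))


@dataclass
class DistanceMatrix:
    """Symmetric accession-level distance matrix."""

    sequence_ids: list[str]
    values: np.ndarray
    metric: str  # "p" | "euclid"
    k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sequence_ids, columns=self.sequence_ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.sequence_ids)}\n")
            for sid, row in zip(self.sequence_ids, self.values):
                fh.write(sid.replace(" ", "_"))
                fh.write("".join(f"  {v:.6f}" for v in row))
                fh.write("\n")


def p_distance_matrix(ds: BarcodeDataset) -> DistanceMatrix:
    """All-vs-all uncorrected p-distances (vectorised, pairwise deletion)."""
    width = ds.alignment_width  # raises if unequal lengths
    enc = np.stack([_encode(r.residues) for r in ds.records])
    valid = enc != 255
    n = len(ds.records)
    vals = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        comp = both.sum(axis=1)
        diff = ((enc[i] != enc) & both).sum(axis=1)
        if np.any(comp == 0):
            j = int(np.nonzero(comp == 0)[0][0])
            if j != i:
                raise UndefinedDistanceError(
                    f"no comparable sites between records {i} and {j}"
                )
        with np.errstate(invalid="ignore"):
            vals[i] = np.where(comp > 0, diff / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix([r.label for r in ds.records], vals, "p")


def euclidean_distance_matrix(
    ds: BarcodeDataset, k: int, denominator: str = "length"
) -> DistanceMatrix:
    """All-vs-all Euclidean distances between accession k-mer profiles."""
    vecs = np.stack(
        [kmer_frequencies(r.residues, k, denominator).vector for r in ds.records]
    )
    diff = vecs[:, None, :] - vecs[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix([r.label for r in ds.records], vals, "euclid", k=k)


@dataclass
class SpeciesResolutionResult:
    """Per-species barcoding-gap outcomes for one metric."""

    metric: str
    flags: dict[str, bool | None]  # None = not evaluable (<2 accessions)
    percent: float

    @property
    def evaluable(self) -> list[str]:
        return [s for s, f in self.flags.items() if f is not None]


def distance_resolution(
    ds: BarcodeDataset,
    metric: str = "p",
    k: int | None = None,
    min_accessions: int = 2,
) -> SpeciesResolutionResult:
    """Barcoding-gap criterion per species.

    A species with at least ``min_accessions`` accessions is resolved iff its
    minimum interspecific distance is strictly greater than its maximum
    intraspecific distance.
    """
    if metric == "p":
        dm = p_distance_matrix(ds)
    elif metric == "euclid":
        if k is None:
            raise ConfigError("euclid metric requires k")
        dm = euclidean_distance_matrix(ds, k)
    else:
        raise ConfigError(f"unknown metric {metric!r}")
    species = np.array([r.species_id for r in ds.records])
    flags: dict[str, bool | None] = {}
    n_eval = n_resolved = 0
    for sp in ds.species_ids:
        own = species == sp
        if own.sum() < min_accessions:
            flags[sp] = None
            continue
        intra = dm.values[np.ix_(own, own)]
        iu = np.triu_indices(int(own.sum()), 1)
        max_intra = float(intra[iu].max())
        inter = dm.values[np.ix_(own, ~own)]
        min_inter = float(inter.min())
        ok = min_inter > max_intra
        flags[sp] = ok
        n_eval += 1
        n_resolved += ok
    if n_eval == 0:
        raise UndefinedScoreError("no species with enough accessions")
    return SpeciesResolutionResult(
        metric=metric, flags=flags, percent=100.0 * n_resolved / n_eval
    )
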