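"""Cross-method comparison and correlation statistics.

Computes, on one dataset, the percent species resolution of six criteria
(p-distance, Euclidean distance of di- and trinucleotide frequencies,
diagnostic characters, and di-/trinucleotide OFR) plus pair-level deltas:
the excess of a pair's minimum interspecific distance over the larger of the
two species' maximum intraspecific distances, and the number of k-mers with
non-overlapping frequency ranges.  Pearson correlations of the p-distance
deltas against the Euclidean deltas and against the OFR counts summarise how
the criteria co-vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _st

from .characters import character_resolution
from .distances import (
    distance_resolution,
    euclidean_distance_matrix,
    p_distance_matrix,
)
from .errors import ConfigError, UndefinedScoreError
from .ofr_core import (
    percent_resolution,
    resolution_matrix,
    species_ofr,
    threshold,
)
from .seqdata import BarcodeDataset, degap


def pearson(xs, ys) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ConfigError("pearson requires two equal-length vectors")
    if xs.size < 3:
        raise ConfigError("pearson requires at least 3 observations")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise UndefinedScoreError("zero variance; correlation undefined")
    r, p = _st.pearsonr(xs, ys)
    return float(r), float(p)


def arcsine_transform(percent) -> np.ndarray:
    """arcsin(sqrt(p/100)) variance-stabilising transform for percentages."""
    arr = np.asarray(percent, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ConfigError("percentages must lie in [0, 100]")
    return np.arcsin(np.sqrt(arr / 100.0))


def pairwise_deltas(
    ds: BarcodeDataset, k: int, min_accessions: int = 2
) -> pd.DataFrame:
    """Per-pair barcoding-gap deltas and non-overlapping OFR counts.

    For each evaluable species pair: ``p_delta`` = (minimum interspecific
    p-distance between the two species) − (maximum intraspecific p-distance
    within either); ``euclid_delta`` analogous on k-mer profiles; ``n_ofr``
    = number of oligos whose ranges are separated by at least t.
    Requires an alignment-consistent dataset (equal gapped lengths).
    """
    pdm = p_distance_matrix(ds)
    ds_plain = degap(ds)
    edm = euclidean_distance_matrix(ds_plain, k)
    ts = threshold(ds_plain.average_length, k)
    profiles = {
        sp: species_ofr(ds_plain, sp, k) for sp in ds_plain.species_ids
    }
    species = np.array([r.species_id for r in ds.records])
    rows = []
    for a, b in combinations(ds.species_ids, 2):
        ia, ib = species == a, species == b
        if ia.sum() < min_accessions or ib.sum() < min_accessions:
            continue

        def delta(vals: np.ndarray) -> float:
            inter = vals[np.ix_(ia, ib)].min()
            iu_a = np.triu_indices(int(ia.sum()), 1)
            iu_b = np.triu_indices(int(ib.sum()), 1)
            intra = max(
                vals[np.ix_(ia, ia)][iu_a].max(),
                vals[np.ix_(ib, ib)][iu_b].max(),
            )
            return float(inter - intra)

        gaps = np.maximum(
            profiles[b].lo - profiles[a].hi, profiles[a].lo - profiles[b].hi
        )
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "p_delta": delta(pdm.values),
                "euclid_delta": delta(edm.values),
                "n_ofr": int((gaps >= ts.t - 1e-12).sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MethodComparison:
    """Six-method resolution percentages plus delta correlations."""

    percents: dict[str, float]
    correlations: dict[str, tuple[float, float]]
    deltas: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"method": m, "percent_resolution": v} for m, v in self.percents.items()]
        )


def compare_methods(
    ds: BarcodeDataset, min_accessions: int = 2, delta_k: int = 3
) -> MethodComparison:
    """Run all six criteria on the same records and correlate their deltas.

    OFR and Euclidean criteria run on the degapped view; p-distance and
    characters on the aligned view.  All percents are species-mode scores.
    ``delta_k`` selects the k-mer size for the pair-level delta table used in
    the two Pearson correlations (trinucleotides by default).
    """
    plain = degap(ds)
    percents: dict[str, float] = {}
    percents["p_distance"] = distance_resolution(
        ds, "p", min_accessions=min_accessions
    ).percent
    for name, k in (("euclid_di", 2), ("euclid_tri", 3)):
        percents[name] = distance_resolution(
            plain, "euclid", k=k, min_accessions=min_accessions
        ).percent
    _, pct_char = character_resolution(ds, min_accessions=min_accessions)
    percents["characters"] = pct_char
    for name, k in (("ofr_di", 2), ("ofr_tri", 3)):
        rm = resolution_matrix(plain, k, min_accessions=min_accessions)
        percents[name] = percent_resolution(rm, mode="species")
    deltas = pairwise_deltas(ds, delta_k, min_accessions=min_accessions)
    correlations: dict[str, tuple[float, float]] = {}
    if len(deltas) >= 3:
        try:
            correlations["p_vs_euclid"] = pearson(
                deltas["p_delta"], deltas["euclid_delta"]
            )
            correlations["p_vs_n_ofr"] = pearson(
                deltas["p_delta"], deltas["n_ofr"]
            )
        except UndefinedScoreError:
            pass
    return MethodComparison(percents=percents, correlations=correlations, deltas=deltas)
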