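"""Simple diagnostic-character species discrimination.

A *pure* character at an alignment column is a nucleotide state fixed in all
accessions of the focal species and absent from the comparison species; a
*private* character is present in some (but not all) focal accessions and
absent from the comparison species.  Columns where any involved accession
carries a gap or ambiguity code are skipped, and gaps never serve as states.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .ofr_core import PairResolution, ResolutionMatrix, ThresholdSpec, percent_resolution
from .seqdata import BarcodeDataset

_STATES = frozenset("ACGT")


@dataclass(frozen=True)
class CharacterDiagnosis:
    """One diagnostic state at one alignment column (0-based)."""

    column: int
    state: str
    focal_species: str
    kind: str  # "pure" | "private"

    @property
    def position(self) -> int:
        """1-based column for reporting."""
        return self.column + 1


def _require_aligned(ds: BarcodeDataset) -> int:
    try:
        return ds.alignment_width
    except AlignmentError:
        raise AlignmentError(
            "character analysis requires equal-length (aligned) records"
        ) from None


def diagnostic_characters(
    ds: BarcodeDataset, species_a: str, species_b: str
) -> list[CharacterDiagnosis]:
    """Scan every alignment column for pure/private characters of a pair."""
    width = _require_aligned(ds)
    idx = ds.species_index
    for sp in (species_a, species_b):
        if sp not in idx:
            raise ConfigError(f"unknown species {sp!r}")
    rows_a = [r.residues for r in idx[species_a]]
    rows_b = [r.residues for r in idx[species_b]]
    out: list[CharacterDiagnosis] = []
    for c in range(width):
        col_a = [s[c] for s in rows_a]
        col_b = [s[c] for s in rows_b]
        if any(ch not in _STATES for ch in col_a + col_b):
            continue  # gap or ambiguity anywhere -> column skipped
        set_a, set_b = set(col_a), set(col_b)
        for focal, states, other in (
            (species_a, set_a, set_b),
            (species_b, set_b, set_a),
        ):
            for st in sorted(states - other):
                kind = "pure" if len(states) == 1 else "private"
                out.append(CharacterDiagnosis(c, st, focal, kind))
    return out


def diagnoses_table(diags: list[CharacterDiagnosis]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": d.position,
                "state": d.state,
                "focal_species": d.focal_species,
                "kind": d.kind,
            }
            for d in diags
        ]
    )


def character_resolution(
    ds: BarcodeDataset,
    require: str = "pure",
    min_accessions: int = 2,
) -> tuple[ResolutionMatrix, float]:
    """Pairwise character-based resolution matrix plus percent resolution.

    A pair is resolved when either species shows at least one pure character
    (``require="pure"``, default) or at least one pure-or-private character
    (``require="pure_or_private"``).
    """
    if require not in ("pure", "pure_or_private"):
        raise ConfigError(f"unknown requirement {require!r}")
    _require_aligned(ds)
    if ds.species_count < 2:
        raise ConfigError("resolution requires at least two species")
    ids = ds.species_ids
    counts = ds.accession_counts
    m = len(ids)
    cells = np.full((m, m), np.nan)
    evidence: dict[frozenset, PairResolution] = {}
    for i, j in combinations(range(m), 2):
        a, b = ids[i], ids[j]
        if counts[a] < min_accessions or counts[b] < min_accessions:
            pr = PairResolution(a, b, "not_evaluable")
        else:
            diags = diagnostic_characters(ds, a, b)
            if require == "pure":
                diags = [d for d in diags if d.kind == "pure"]
            pr = PairResolution(
                a,
                b,
                "resolved" if diags else "unresolved",
                discriminating_oligos=[
                    (f"{d.position}{d.state}", 0.0) for d in diags
                ],
            )
        evidence[frozenset((a, b))] = pr
        val = np.nan if pr.status == "not_evaluable" else float(pr.resolved)
        cells[i, j] = cells[j, i] = val
    # character matrices carry no frequency threshold; record a placeholder
    ts = ThresholdSpec(k=1, average_length=ds.average_length + 1)
    rm = ResolutionMatrix(ids, cells, evidence, ts)
    return rm, percent_resolution(rm, mode="species")
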