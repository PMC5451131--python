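"""Core in-memory containers shared across the pipeline.

Conventions: animal and marker identifiers are strings; unknown parents are
coded ``0`` on disk and ``-1`` as an integer index in memory; genotype
dosages count copies of the second (B) allele and are stored marker-major
(rows = markers, columns = animals) with ``NaN`` for missing; base-pair
positions are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1


@dataclass
class Pedigree:
    """Ordered pedigree: parents always precede offspring.

    ``df`` columns: animal, sire, dam (identifier strings, "0" = unknown),
    generation (int), sex ("M"/"F").
    """

    df: pd.DataFrame
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        required = {"animal", "sire", "dam", "generation"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        ids = self.df["animal"].tolist()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate animal identifiers in pedigree")
        self._index = {a: i for i, a in enumerate(ids)}
        seen = set()
        for row in self.df.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent != "0" and parent not in seen:
                    if parent not in self._index:
                        raise ValueError(
                            f"parent {parent!r} of {row.animal!r} never appears as an animal"
                        )
                    raise ValueError(
                        f"parent {parent!r} listed after offspring {row.animal!r}"
                    )
            seen.add(row.animal)

    @property
    def n_animals(self) -> int:
        return len(self.df)

    @property
    def animal_ids(self) -> list[str]:
        return self.df["animal"].tolist()

    def indices(self, animal_ids) -> np.ndarray:
        """Integer positions of the given animals in pedigree order."""
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"animal {exc.args[0]!r} not in pedigree") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire, dam) integer index arrays, ``-1`` for unknown."""
        sires = np.array(
            [self._index[s] if s != "0" else UNKNOWN for s in self.df["sire"]],
            dtype=np.int64,
        )
        dams = np.array(
            [self._index[d] if d != "0" else UNKNOWN for d in self.df["dam"]],
            dtype=np.int64,
        )
        return sires, dams


@dataclass
class GenotypePanel:
    """Marker-major dosage panel with per-genotype quality scores.

    dosages: (n_markers, n_animals) float array over {0,1,2,NaN}.
    quality: same shape, scores in [0,1] (role of the Illumina GC score).
    marker_map: DataFrame with columns chrom (str; autosomes are numeric
    strings), marker_id, bp (1-based int).
    """

    dosages: np.ndarray
    quality: np.ndarray
    marker_map: pd.DataFrame
    animal_ids: list[str]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.dosages.shape != self.quality.shape:
            raise ValueError("dosages and quality must have identical shape")
        if len(self.marker_map) != self.dosages.shape[0]:
            raise ValueError("marker map length must equal marker count")
        if len(self.animal_ids) != self.dosages.shape[1]:
            raise ValueError("animal_ids length must equal animal count")
        if len(self.marker_map) and (self.marker_map["bp"] < 1).any():
            raise ValueError("bp positions are 1-based and must be >= 1")
        grouped = self.marker_map.groupby("chrom", sort=False)["bp"]
        if not all(g.is_monotonic_increasing for _, g in grouped):
            raise ValueError("marker map not sorted by (chromosome, bp); sort it first")

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return self.marker_map["marker_id"].tolist()

    def allele_frequencies(self) -> np.ndarray:
        """Second-allele frequency p_i per marker from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=1) / 2.0

    def subset(self, marker_mask=None, animal_mask=None) -> "GenotypePanel":
        d, q, m, a = self.dosages, self.quality, self.marker_map, self.animal_ids
        if marker_mask is not None:
            d, q = d[marker_mask], q[marker_mask]
            m = m.loc[np.asarray(marker_mask)].reset_index(drop=True)
        if animal_mask is not None:
            d, q = d[:, animal_mask], q[:, animal_mask]
            a = [x for x, keep in zip(a, animal_mask) if keep]
        return GenotypePanel(d.copy(), q.copy(), m.copy(), list(a))


#: columns every phenotype table carries; trait is categorical {0,1} or {0,1,2}
PHENOTYPE_COLUMNS = [
    "animal",
    "trait",
    "herd",
    "birth_year",
    "birth_season",
    "weaning_group",
    "yearling_group",
    "age_first_calving",
    "age_second_calving",
    "calving_interval",
]


def validate_phenotypes(df: pd.DataFrame, n_categories: int | None = None) -> None:
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    values = set(df["trait"].dropna().unique())
    allowed = set(range(n_categories)) if n_categories else {0, 1, 2}
    if not values <= allowed:
        raise ValueError(f"trait values {values - allowed} outside category set")
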