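"""Feature-table container: phylotype x library counts with sample metadata.

The count matrix (rows = phylotypes, columns = libraries) is the common
currency of all community analyses in this package.  Metadata rows describe
each library (isotope label, gradient fraction, buoyant density, ecoplot,
replicate, assay).  Taxonomy strings ride along as a per-phylotype Series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns a SIP sample sheet is expected to carry (missing ones are allowed
#: to be absent for non-gradient assays)
SAMPLE_COLUMNS = (
    "isotope",
    "fraction_id",
    "density",
    "ecoplot",
    "replicate",
    "assay",
)

DENSITY_BOUNDS = (1.5, 1.9)  # plausible CsCl buoyant densities, g/mL


class FeatureTableError(ValueError):
    """Malformed feature table or metadata mismatch."""


@dataclass
class FeatureTable:
    """Phylotype x library count matrix plus per-library metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, index = phylotype ids, columns =
        library ids.
    samples : DataFrame
        One row per library (index = library id).
    taxonomy : Series, optional
        Taxonomy string per phylotype (semicolon-delimited ranks).
    rarefied_depth : int, optional
        Set by :func:`isoprime.sip.rarefy`; downstream diversity metrics
        require it.
    normalized : str, optional
        Name of the normalization applied ("cpt", "median-of-ratios", ...);
        None for raw counts.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    taxonomy: pd.Series | None = None
    rarefied_depth: int | None = None
    normalized: str | None = None
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FeatureTableError(f"duplicated phylotype ids: {list(dups)}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise FeatureTableError(f"duplicated library ids: {list(dups)}")
        missing = self.counts.columns.difference(self.samples.index)
        if len(missing):
            raise FeatureTableError(
                f"libraries without sample metadata: {list(missing)}"
            )
        if self.normalized is None:
            arr = self.counts.to_numpy()
            if np.any(arr < 0):
                raise FeatureTableError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise FeatureTableError("raw counts must be integers")
        if "density" in self.samples.columns:
            dens = pd.to_numeric(self.samples["density"], errors="coerce").dropna()
            lo, hi = DENSITY_BOUNDS
            bad = dens[(dens <= lo) | (dens >= hi)]
            if len(bad):
                raise FeatureTableError(
                    f"buoyant densities outside plausible CsCl range {DENSITY_BOUNDS}:"
                    f" {bad.to_dict()}"
                )
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
        self._validated = True

    # -- convenience -------------------------------------------------------

    @property
    def phylotypes(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns

    def library_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-library relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            zero = totals.index[totals == 0].tolist()
            raise FeatureTableError(f"all-zero libraries: {zero}")
        return self.counts / totals

    def subset_libraries(self, library_ids) -> "FeatureTable":
        ids = [lib for lib in self.counts.columns if lib in set(library_ids)]
        return FeatureTable(
            counts=self.counts[ids].copy(),
            samples=self.samples.loc[ids].copy(),
            taxonomy=None if self.taxonomy is None else self.taxonomy.copy(),
            rarefied_depth=self.rarefied_depth,
            normalized=self.normalized,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            counts=self.counts.copy(),
            samples=self.samples.copy(),
            taxonomy=None if self.taxonomy is None else self.taxonomy.copy(),
            rarefied_depth=self.rarefied_depth,
            normalized=self.normalized,
        )
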