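"""DNA-SIP enrichment calling and community summaries.

A phylotype is called a 13C-substrate degrader when its mean normalized
abundance in the heavy CsCl window (fractions F3-F8, ~1.74-1.76 g/mL) is
at least eightfold greater in 13C-labeled than in 12C-control gradient
libraries (log2 fold change >= 3, boundary inclusive).  Normalization is
either counts-per-thousand or a median-of-ratios size-factor scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.alpha import pielou_e, shannon

from .table import FeatureTable, FeatureTableError

DEFAULT_HEAVY_WINDOW = ("F3", "F4", "F5", "F6", "F7", "F8")
DEFAULT_RAREFACTION_DEPTH = 9140
DEFAULT_FOLD_THRESHOLD = 8.0
DEFAULT_PSEUDOCOUNT = 0.5


class SipError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    phylotype: str
    mean_13c: float
    mean_12c: float
    log2_fold_change: float
    enriched: bool
    pseudocount: float


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def filter_phylotypes(table: FeatureTable, blank_ids=(),
                      min_total_fraction: float = 0.0005,
                      min_samples: int = 3,
                      ) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove contaminant, rare, and sporadic phylotypes.

    Drops phylotypes (i) detected in any reagent-blank library, (ii) whose
    share of all sequences is below ``min_total_fraction`` (default
    0.05 %), or (iii) present in fewer than ``min_samples`` libraries.
    Blank libraries themselves are dropped from the returned table.  Also
    returns a removal ledger (phylotype, reason).
    """
    if not 0.0 <= min_total_fraction <= 1.0:
        raise SipError("min_total_fraction outside [0, 1]")
    if min_samples < 0:
        raise SipError("negative min_samples")
    blanks = list(blank_ids)
    missing = set(blanks) - set(table.libraries)
    if missing:
        raise SipError(f"blank libraries not in table: {sorted(missing)}")

    counts = table.counts
    in_blanks = counts[blanks].sum(axis=1) > 0 if blanks else \
        pd.Series(False, index=counts.index)
    non_blank = counts.drop(columns=blanks)
    grand_total = non_blank.to_numpy().sum()
    share = non_blank.sum(axis=1) / grand_total if grand_total > 0 else \
        pd.Series(0.0, index=counts.index)
    prevalence = (non_blank > 0).sum(axis=1)

    ledger_rows = []
    for pid in counts.index:
        reasons = []
        if in_blanks[pid]:
            reasons.append("in_blank")
        if share[pid] < min_total_fraction:
            reasons.append("low_abundance")
        if prevalence[pid] < min_samples:
            reasons.append("few_samples")
        if reasons:
            ledger_rows.append({"phylotype": pid, "reason": ";".join(reasons)})
    ledger = pd.DataFrame(ledger_rows, columns=["phylotype", "reason"])
    keep = counts.index.difference(ledger["phylotype"], sort=False)
    if len(keep) == 0:
        warnings.warn("all phylotypes removed by filtering", stacklevel=2)
    filtered = FeatureTable(
        counts=non_blank.loc[keep],
        samples=table.samples.drop(index=blanks),
        taxonomy=None if table.taxonomy is None else table.taxonomy.loc[keep],
    )
    return filtered, ledger


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-library size factor: median over phylotypes of count / geometric
    row mean, computed on phylotypes with strictly positive counts in every
    library (the standard median-of-ratios estimator)."""
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise SipError("no phylotype with positive counts in every library; "
                       "cannot compute median-of-ratios size factors")
    sub = arr[all_pos]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(table: FeatureTable, mode: str = "cpt",
                     pseudocount: float = DEFAULT_PSEUDOCOUNT,
                     ) -> tuple[FeatureTable, pd.Series | None]:
    """Normalize a count table.

    ``cpt`` scales every library to sum to 1000 (counts per thousand).
    ``median-of-ratios`` divides each library by its size factor;
    ``median-of-ratios-log`` additionally applies log2(x + pseudocount),
    a variance-stabilizing transform for the heavy-window comparison.
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).all():
        raise SipError("no non-zero library to normalize")
    if mode == "cpt":
        zero = totals.index[totals == 0].tolist()
        if zero:
            raise SipError(f"all-zero libraries: {zero}")
        norm = table.counts / totals * 1000.0
        sf = None
    elif mode in ("median-of-ratios", "median-of-ratios-log"):
        sf = median_of_ratios_size_factors(table.counts)
        norm = table.counts / sf
        if mode.endswith("log"):
            norm = np.log2(norm + pseudocount)
    else:
        raise SipError(f"unknown normalization mode: {mode}")
    out = FeatureTable(counts=norm, samples=table.samples.copy(),
                       taxonomy=table.taxonomy, normalized=mode)
    return out, sf


# ---------------------------------------------------------------------------
# heavy-window fold change
# ---------------------------------------------------------------------------


def select_heavy_window(samples: pd.DataFrame, window) -> pd.Index:
    """Libraries in the heavy window, by fraction ids or density bounds.

    ``window`` is either an iterable of fraction ids (e.g. F3..F8) or a
    (density_lo, density_hi) pair in g/mL.
    """
    if len(window) == 2 and all(isinstance(w, (int, float)) for w in window):
        lo, hi = sorted(window)
        dens = pd.to_numeric(samples["density"], errors="coerce")
        mask = (dens >= lo) & (dens <= hi)
    else:
        wanted = set(window)
        mask = samples["fraction_id"].isin(wanted)
    return samples.index[mask]


def heavy_window_fold_change(table: FeatureTable,
                             window=DEFAULT_HEAVY_WINDOW,
                             pseudocount: float = DEFAULT_PSEUDOCOUNT,
                             fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
                             norm: str = "cpt") -> pd.DataFrame:
    """Per-phylotype heavy-window log2 fold change, 13C versus 12C.

    Counts are normalized (``cpt`` or ``median-of-ratios``), averaged over
    the heavy-window libraries of each isotope arm, and compared as
    log2((mean_13C + pc) / (mean_12C + pc)).  Phylotypes at or above
    log2(fold_threshold) are flagged enriched ("at least eightfold").
    Results are sorted by descending fold change.
    """
    if "isotope" not in table.samples.columns:
        raise SipError("sample sheet lacks an 'isotope' column")
    libs = select_heavy_window(table.samples, window)
    if len(libs) == 0:
        raise SipError(f"empty heavy window: {window}")
    iso = table.samples.loc[libs, "isotope"]
    libs_13 = libs[iso == "13C"]
    libs_12 = libs[iso == "12C"]
    if len(libs_13) == 0 or len(libs_12) == 0:
        raise SipError("heavy window must contain both 13C and 12C libraries")
    if norm == "cpt":
        normed, _ = normalize_counts(table, mode="cpt")
    elif norm == "median-of-ratios":
        normed, _ = normalize_counts(table, mode="median-of-ratios")
    else:
        raise SipError(f"unsupported normalization for fold change: {norm}")
    m13 = normed.counts[libs_13].mean(axis=1)
    m12 = normed.counts[libs_12].mean(axis=1)
    if pseudocount <= 0 and ((m12 == 0) | (m13 == 0)).any():
        raise SipError("zero means need a positive pseudocount")
    log2fc = np.log2((m13 + pseudocount) / (m12 + pseudocount))
    out = pd.DataFrame({
        "phylotype": table.phylotypes,
        "mean_13c": m13.to_numpy(),
        "mean_12c": m12.to_numpy(),
        "log2_fold_change": log2fc.to_numpy(),
        "enriched": (log2fc >= np.log2(fold_threshold)).to_numpy(),
        "pseudocount": pseudocount,
    }).set_index("phylotype")
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    return out.sort_values("log2_fold_change", ascending=False)


# ---------------------------------------------------------------------------
# rarefaction and diversity
# ---------------------------------------------------------------------------


def rarefy(table: FeatureTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | None = None,
           rng: np.random.Generator | None = None,
           ) -> tuple[FeatureTable, list[str]]:
    """Subsample every library to exactly ``depth`` reads without replacement.

    Libraries with fewer than ``depth`` reads are dropped and listed.
    Sampling is multivariate hypergeometric and deterministic given the
    seed.  Returns (rarefied table, dropped library ids).
    """
    if depth < 1:
        raise SipError("rarefaction depth must be >= 1")
    if rng is None:
        if seed is None:
            raise SipError("a seed (or generator) is required for rarefaction")
        rng = np.random.default_rng(seed)
    totals = table.library_totals()
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if not keep:
        raise SipError(f"all libraries below rarefaction depth {depth}")
    cols = {}
    for lib in keep:
        col = table.counts[lib].to_numpy(dtype=np.int64)
        if col.sum() == depth:
            cols[lib] = col
        else:
            cols[lib] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    rare = pd.DataFrame(cols, index=table.phylotypes)
    out = FeatureTable(counts=rare, samples=table.samples.loc[keep].copy(),
                       taxonomy=table.taxonomy, rarefied_depth=int(depth))
    return out, dropped


def diversity_metrics(table: FeatureTable) -> pd.DataFrame:
    """Richness, Shannon H (natural log) and Pielou evenness per library.

    Requires a rarefied table so the metrics are comparable across
    libraries; J is undefined (NaN) for single-taxon libraries.
    """
    if table.rarefied_depth is None:
        raise SipError("diversity metrics require a rarefied table")
    rows = []
    for lib in table.libraries:
        counts = table.counts[lib].to_numpy(dtype=np.int64)
        if counts.sum() == 0:
            raise SipError(f"zero-total library: {lib}")
        s = int((counts > 0).sum())
        h = float(shannon(counts, base=np.e))
        j = float(pielou_e(counts)) if s > 1 else np.nan
        rows.append({"library_id": lib, "richness": s, "shannon_h": h,
                     "pielou_j": j, "rarefaction_depth": table.rarefied_depth})
    return pd.DataFrame(rows).set_index("library_id")


def taxon_group_share(table: FeatureTable, patterns) -> pd.Series:
    """Per-library summed relative abundance of phylotypes whose taxonomy
    matches any of the given substrings (e.g. genus names)."""
    pats = list(patterns)
    if not pats:
        raise SipError("empty taxonomy pattern set")
    if table.taxonomy is None:
        raise FeatureTableError("table has no taxonomy")
    tax = table.taxonomy.fillna("")
    mask = pd.Series(False, index=table.phylotypes)
    for p in pats:
        mask |= tax.str.contains(p, regex=False)
    if not mask.any():
        warnings.warn(f"no phylotype matches patterns {pats}", stacklevel=2)
        return pd.Series(0.0, index=table.libraries, name="share")
    rel = table.relative_abundance()
    return rel.loc[mask].sum(axis=0).rename("share")
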