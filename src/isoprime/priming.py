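"""Two-pool 13C source partitioning and priming-effect estimation.

Respired CO2 is split into amendment-derived and SOC-derived carbon with
the two-member isotope mixing line

    f_sub = (F_sample - F_nat) / (F_sub - F_nat)

where F_sample is the measured 13C atom fraction of respired CO2, F_sub
the atom fraction of the added substrate (0.175 in microcosms, 0.99 in
field dosings) and F_nat the natural-abundance baseline estimated from
unlabeled controls.  Primed SOC is the native SOC respired in excess of
water-only controls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import NATURAL_ABUNDANCE_13C


class PartitionError(ValueError):
    pass


@dataclass
class IntervalPartition:
    """One vial-interval's respired C split into substrate and SOC pools."""

    vial_id: str
    t_start: float
    t_end: float
    total_c: float
    f_sample: float
    f_sub_fraction: float  # mixing fraction in [0, 1]
    c_sub: float
    c_soc: float
    clamped: bool


@dataclass
class PrimingSeries:
    """Per-treatment priming summary against water-only controls.

    ``per_time`` columns: time_h, mean_c_sub, sd_c_sub, mean_c_soc,
    sd_c_soc, control_mean_total, primed_c, cum_primed_c, welch_p,
    significant.  ``percent_priming`` is 100 x cumulative primed /
    cumulative control respiration at the final timepoint.
    """

    treatment: str
    ecoplot: str | None
    per_time: pd.DataFrame
    cumulative_primed_c: float
    percent_priming: float


@dataclass
class TreatmentComparison:
    """One-way ANOVA with Tukey HSD pairwise tests and letter display."""

    groups: list[str]
    means: pd.Series
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # group1, group2, mean_diff, q_stat, p_adj
    letters: dict[str, str]


# ---------------------------------------------------------------------------
# baselines and net 13CO2
# ---------------------------------------------------------------------------


def natural_abundance_baseline(control_measurements: pd.DataFrame,
                               strata: tuple[str, ...] | None = ("ecoplot",),
                               fallback: float = NATURAL_ABUNDANCE_13C,
                               ) -> pd.Series:
    """Mean 13C atom fraction of CO2 respired by unlabeled controls.

    Returns a Series indexed by stratum (or a single ``"pooled"`` entry
    when ``strata`` is None).  Controls with zero total CO2 are excluded;
    if nothing usable remains the constant natural-abundance fallback is
    returned with a warning.
    """
    df = control_measurements.copy()
    total = df["umol12_per_g"] + df["umol13_per_g"]
    df = df.loc[total > 0]
    if df.empty:
        warnings.warn(
            f"no usable controls; falling back to constant F_nat = {fallback}",
            stacklevel=2,
        )
        return pd.Series({"pooled": fallback}, name="f_nat")
    frac = df["umol13_per_g"] / (df["umol12_per_g"] + df["umol13_per_g"])
    if strata is None:
        return pd.Series({"pooled": float(frac.mean())}, name="f_nat")
    return frac.groupby([df[c] for c in strata]).mean().rename("f_nat")


def net_13co2(labeled: pd.DataFrame, controls: pd.DataFrame,
              strata: tuple[str, ...] = ("ecoplot",)) -> pd.DataFrame:
    """Net 13CO2: labeled 13CO2 minus mean control 13CO2, per timepoint.

    Labeled and control tables must cover the same (stratum, time) cells;
    negative net values are retained and flagged.
    """
    keys = list(strata) + ["time_h"]
    ctrl_mean = controls.groupby(keys)["umol13_per_g"].mean().rename("control_13co2")
    out = labeled.merge(ctrl_mean, left_on=keys, right_index=True, how="left")
    if out["control_13co2"].isna().any():
        missing = out.loc[out["control_13co2"].isna(), keys].drop_duplicates()
        raise PartitionError(
            f"no control measurements for strata:\n{missing.to_string(index=False)}"
        )
    out["net_13co2"] = out["umol13_per_g"] - out["control_13co2"]
    out["negative"] = out["net_13co2"] < 0
    return out


# ---------------------------------------------------------------------------
# the mixing model
# ---------------------------------------------------------------------------


def partition_interval(total_c: float, f_sample: float, f_sub: float,
                       f_nat: float, vial_id: str = "", t_start: float = np.nan,
                       t_end: float = np.nan) -> IntervalPartition:
    """Two-source mixing split of one interval's respired C.

    The mixing fraction is clamped to [0, 1] (noise can push the measured
    atom fraction outside the mixing line) and the clamp is flagged.
    """
    if f_sub <= f_nat:
        raise PartitionError(
            f"unidentifiable mixture: F_sub ({f_sub}) must exceed F_nat ({f_nat})"
        )
    if total_c < 0:
        raise PartitionError(f"negative total C: {total_c}")
    raw = (f_sample - f_nat) / (f_sub - f_nat)
    clamped = bool(raw < 0.0 or raw > 1.0)
    f = min(max(raw, 0.0), 1.0)
    c_sub = f * total_c
    c_soc = total_c - c_sub
    # the split defines the carbon accounting: C_sub + C_soc = total exactly
    return IntervalPartition(
        vial_id=vial_id, t_start=t_start, t_end=t_end, total_c=c_sub + c_soc,
        f_sample=f_sample, f_sub_fraction=f, c_sub=c_sub,
        c_soc=c_soc, clamped=clamped,
    )


def partition_table(measurements: pd.DataFrame, f_sub: float,
                    f_nat: float | pd.Series,
                    strata: tuple[str, ...] = ("ecoplot",)) -> pd.DataFrame:
    """Apply the mixing model to a quantified measurement table.

    ``f_nat`` may be a scalar or a Series indexed by stratum (output of
    :func:`natural_abundance_baseline`).  Rows are assumed to be interval
    measurements (headspace flushed between samplings), sorted by time
    within each vial.
    """
    df = measurements.copy()
    if isinstance(f_nat, pd.Series):
        if len(strata) == 1:
            df["f_nat"] = df[strata[0]].map(f_nat)
        else:
            idx = pd.MultiIndex.from_frame(df[list(strata)])
            df["f_nat"] = f_nat.reindex(idx).to_numpy()
        if df["f_nat"].isna().any():
            raise PartitionError("f_nat missing for some strata")
    else:
        df["f_nat"] = float(f_nat)

    total = df["umol12_per_g"] + df["umol13_per_g"]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_sample = np.where(total > 0, df["umol13_per_g"] / total, df["f_nat"])
    raw = (f_sample - df["f_nat"]) / (f_sub - df["f_nat"])
    if np.any(f_sub <= df["f_nat"]):
        raise PartitionError("unidentifiable mixture: F_sub <= F_nat")
    clamped = (raw < 0) | (raw > 1)
    f = np.clip(raw, 0.0, 1.0)
    df["f_sample"] = f_sample
    df["f_sub_fraction"] = f
    df["c_sub"] = f * total
    df["c_soc"] = total - df["c_sub"]
    # the split defines the carbon accounting: C_sub + C_soc = total exactly
    df["total_c"] = df["c_sub"] + df["c_soc"]
    df["clamped"] = clamped
    return df


def accumulate_series(partitions: pd.DataFrame,
                      by: tuple[str, ...] = ("vial_id",)) -> pd.DataFrame:
    """Running sums of C_sub / C_soc / total per vial over sorted intervals.

    Headspace flushing makes intervals additive, so cumulative emission at
    each sampling time is the plain running sum.  Raises if intervals
    overlap within a vial.
    """
    if partitions.empty:
        return partitions.copy()
    df = partitions.sort_values(list(by) + ["time_h"]).copy()
    if "t_start" in df.columns and "t_end" in df.columns:
        for _, grp in df.groupby(list(by)):
            starts, ends = grp["t_start"].to_numpy(), grp["t_end"].to_numpy()
            if np.any(starts[1:] < ends[:-1] - 1e-12):
                raise PartitionError("overlapping intervals")
    g = df.groupby(list(by))
    for col in ("c_sub", "c_soc", "total_c"):
        df[f"cum_{col}"] = g[col].cumsum()
    return df


def primed_soc(treatment_series: pd.DataFrame, control_series: pd.DataFrame,
               treatment: str = "", ecoplot: str | None = None,
               alpha: float = 0.05) -> PrimingSeries:
    """Primed SOC of a treatment relative to water-only controls.

    primed(t) = mean SOC-derived C of the treatment minus mean *total*
    respiration of water controls, per interval; the cumulative series is
    its running sum.  A Welch two-sample test flags timepoints where
    SOC respiration differs from the control at ``alpha``.
    """
    t_times = np.sort(treatment_series["time_h"].unique())
    c_times = np.sort(control_series["time_h"].unique())
    if len(t_times) != len(c_times) or not np.allclose(t_times, c_times):
        raise PartitionError(
            f"timepoint mismatch: treatment {t_times}, control {c_times}"
        )
    if control_series["vial_id"].nunique() < 1:
        raise PartitionError("need at least one control replicate")

    rows = []
    cum_primed = 0.0
    cum_control = 0.0
    for t in t_times:
        trt = treatment_series.loc[treatment_series["time_h"] == t]
        ctl = control_series.loc[control_series["time_h"] == t]
        ctl_total = ctl["total_c"]
        primed = trt["c_soc"].mean() - ctl_total.mean()
        cum_primed += primed
        cum_control += ctl_total.mean()
        if len(trt) > 1 and len(ctl) > 1 and \
                (trt["c_soc"].var(ddof=1) > 0 or ctl_total.var(ddof=1) > 0):
            p = float(stats.ttest_ind(trt["c_soc"], ctl_total, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append({
            "time_h": t,
            "mean_c_sub": trt["c_sub"].mean(), "sd_c_sub": trt["c_sub"].std(ddof=1),
            "mean_c_soc": trt["c_soc"].mean(), "sd_c_soc": trt["c_soc"].std(ddof=1),
            "control_mean_total": ctl_total.mean(),
            "primed_c": primed, "cum_primed_c": cum_primed,
            "welch_p": p, "significant": bool(p < alpha) if np.isfinite(p) else False,
        })
    per_time = pd.DataFrame(rows)
    pct = 100.0 * cum_primed / cum_control if cum_control > 0 else np.nan
    return PrimingSeries(
        treatment=treatment, ecoplot=ecoplot, per_time=per_time,
        cumulative_primed_c=float(cum_primed), percent_priming=float(pct),
    )


def substrate_recovery(cum_c_sub: float, dose_c: float) -> tuple[float, bool]:
    """Percent of the amendment respired; values > 100 are flagged, not clipped."""
    if dose_c <= 0:
        raise PartitionError("substrate recovery undefined for zero dose")
    pct = 100.0 * cum_c_sub / dose_c
    return pct, pct > 100.0


# ---------------------------------------------------------------------------
# treatment comparison (ANOVA + Tukey HSD + compact letter display)
# ---------------------------------------------------------------------------


def _compact_letter_display(groups: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    Each maximal clique of the 'not significantly different' graph gets one
    letter; letters are assigned in group order for stability.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from((a, b) for a, b in
                     (tuple(sorted(p)) for p in nonsig_pairs))
    cliques = sorted(nx.find_cliques(g), key=lambda c: (len(c) == 0, sorted(groups.index(x) for x in c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        for grp in clique:
            letters[grp] += alphabet[i % len(alphabet)]
    return {grp: "".join(sorted(v)) for grp, v in letters.items()}


def compare_treatments(values_by_group: dict[str, np.ndarray],
                       alpha: float = 0.05) -> TreatmentComparison:
    """One-way ANOVA with Tukey HSD pairwise adjusted p-values.

    Adjusted p-values come from the studentized range distribution with
    the Tukey-Kramer statistic, so unbalanced designs are handled.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise PartitionError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise PartitionError(f"group {g!r} needs at least two values")
    all_vals = np.concatenate(list(arrays.values()))
    n_total, k = len(all_vals), len(groups)
    df_within = n_total - k
    mse = sum(np.sum((v - v.mean()) ** 2) for v in arrays.values()) / df_within
    if mse <= 0:
        raise PartitionError("degenerate design: zero within-group variance everywhere")

    f_stat, f_p = stats.f_oneway(*arrays.values())
    rows = []
    nonsig = set()
    for g1, g2 in itertools.combinations(groups, 2):
        v1, v2 = arrays[g1], arrays[g2]
        diff = v1.mean() - v2.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / len(v1) + 1.0 / len(v2)))
        q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_within))
        rows.append({"group1": g1, "group2": g2, "mean_diff": diff,
                     "q_stat": q, "p_adj": p_adj})
        if p_adj >= alpha:
            nonsig.add(frozenset((g1, g2)))
    letters = _compact_letter_display(groups, nonsig)
    return TreatmentComparison(
        groups=groups,
        means=pd.Series({g: v.mean() for g, v in arrays.items()}),
        anova_f=float(f_stat), anova_p=float(f_p),
        pairwise=pd.DataFrame(rows), letters=letters,
    )
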