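import dataclasses

import numpy as np
import pandas as pd
import pytest

from isoprime import gcms, priming
from isoprime.simulate import default_microcosm_config
from isoprime.table import FeatureTable


@pytest.fixture
def default_config():
    return default_microcosm_config(seed=7)


@pytest.fixture
def noiseless_config(default_config):
    return dataclasses.replace(default_config, measurement_cv=0.0)


@pytest.fixture
def geometry():
    return gcms.VialGeometry()


@pytest.fixture
def toy_table():
    """3 phylotypes x 4 libraries with taxonomy and a SIP-style sheet."""
    counts = pd.DataFrame(
        {
            "L1": [600, 399, 1],
            "L2": [500, 300, 0],
            "L3": [700, 500, 1],
            "L4": [650, 400, 1],
        },
        index=["asv1", "asv2", "asv3"],
    )
    samples = pd.DataFrame(
        {
            "isotope": ["13C", "13C", "12C", "12C"],
            "fraction_id": ["F3", "F4", "F3", "F4"],
            "density": [1.76, 1.755, 1.76, 1.755],
            "ecoplot": ["RP_LnC"] * 4,
            "replicate": [1, 2, 1, 2],
            "assay": ["DNA-SIP"] * 4,
        },
        index=["L1", "L2", "L3", "L4"],
    )
    taxonomy = pd.Series(
        ["Bacteria;Paraburkholderia;asv1", "Bacteria;Rhodanobacter;asv2",
         "Bacteria;Caballeronia;asv3"],
        index=counts.index,
    )
    return FeatureTable(counts=counts, samples=samples, taxonomy=taxonomy)


def quantify_default(readings, config):
    """Helper: identity-calibration quantification of simulated readings."""
    geom = config.geometry
    return gcms.quantify_table(
        readings,
        gcms.CalibrationCurve.identity(44),
        gcms.CalibrationCurve.identity(45),
        geom,
    )


def control_series(measurements, control="water"):
    """Water-control respiration table shaped for primed_soc."""
    ctrl = measurements.loc[measurements["treatment"] == control].copy()
    ctrl["total_c"] = ctrl["umol12_per_g"] + ctrl["umol13_per_g"]
    ctrl["c_soc"] = ctrl["total_c"]
    ctrl["c_sub"] = 0.0
    return ctrl


def estimate_priming(config, treatments=("pHB", "glucose")):
    """Full estimation chain on one simulated microcosm run."""
    from isoprime.simulate import simulate_microcosm

    readings, truth = simulate_microcosm(config)
    meas = quantify_default(readings, config)
    ctrl = control_series(meas)
    f_nat = priming.natural_abundance_baseline(
        meas.loc[meas["treatment"] == "water"])
    out = {}
    f_subs = {t.name: t.substrate_atom_fraction_13c for t in config.treatments}
    for name in treatments:
        part = priming.partition_table(
            meas.loc[meas["treatment"] == name], f_sub=f_subs[name],
            f_nat=f_nat, strata=("ecoplot",))
        series = priming.primed_soc(part, ctrl, treatment=name)
        out[name] = {
            "series": series,
            "partitions": part,
            "cumulative": priming.accumulate_series(part),
            "truth": truth,
        }
    return out
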