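"""Bundled reference tables from the published method-development study.

All fixtures are small CSV files shipped with the package: the two-factor
CCD factor definitions and 13-run design with measured responses, system
suitability metrics, QC precision/accuracy tables, stability data and the
reported PK parameter summary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .designs import FactorDefinition

__all__ = [
    "load_ccd_design",
    "load_ccd_factors",
    "load_system_suitability",
    "load_qc_precision_accuracy",
    "load_qc_stability",
    "load_pk_parameters",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("doepk.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_ccd_design() -> pd.DataFrame:
    """13-run face-centred CCD with responses Y1 (retention time, min),
    Y2 (peak resolution) and Y3 (peak asymmetry)."""
    return _read("ccd_design_responses.csv")


def load_ccd_factors() -> list[FactorDefinition]:
    """The two chromatographic factors: methanol % (10/20/30) and mobile
    phase pH (2.5/3.5/4.0)."""
    frame = _read("ccd_factors.csv")
    return [
        FactorDefinition(
            name=r["name"],
            symbol=r["symbol"],
            low=float(r["low"]),
            centre=float(r["centre"]),
            high=float(r["high"]),
            units=r["units"],
        )
        for _, r in frame.iterrows()
    ]


def load_system_suitability() -> pd.DataFrame:
    """Reported system-suitability metrics for analyte and internal standard."""
    return _read("system_suitability.csv")


def load_qc_precision_accuracy() -> pd.DataFrame:
    """Intraday/interday QC table: nominal, observed mean +- SD, %RSD, %accuracy."""
    return _read("qc_precision_accuracy.csv")


def load_qc_stability() -> pd.DataFrame:
    """Stability QC table: condition, spiked and measured levels, %accuracy."""
    return _read("qc_stability.csv")


def load_pk_parameters() -> pd.DataFrame:
    """Reported NCA parameter summary (mean, SD) per formulation group."""
    return _read("pk_parameters.csv")
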