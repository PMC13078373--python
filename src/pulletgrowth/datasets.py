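"""Packaged reference data.

``load_strain_parameters`` returns the published monomolecular parameter
estimates (with standard errors) for six commercial layer strains — Hy-Line
W36, Isa Brown, Dekalb White, Bovans White, Bovans Brown and Shaver — fitted
to rearing-period (weeks 1-18) intake/gain profiles.  These 18
(parameter, strain, estimate, se) rows are the input to the meta-analysis
stage when the raw guide profiles themselves are not available.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta import MetaInput, MetaStudy

STRAINS = (
    "Hy-Line W36",
    "Isa Brown",
    "Dekalb White",
    "Bovans White",
    "Bovans Brown",
    "Shaver",
)


def load_strain_parameters() -> pd.DataFrame:
    """Six-strain (estimate, SE) table, columns parameter,strain,estimate,se."""
    with resources.files("pulletgrowth").joinpath(
        "data/strain_parameters.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def strain_parameters_meta_input(parameter: str) -> MetaInput:
    """MetaInput for one monomolecular parameter ('a', 'b' or 'c')."""
    df = load_strain_parameters()
    sub = df[df["parameter"] == parameter]
    if sub.empty:
        raise KeyError(f"unknown parameter {parameter!r}; expected one of a, b, c")
    studies = tuple(
        MetaStudy(label=row.strain, estimate=row.estimate, se=row.se)
        for row in sub.itertuples()
    )
    return MetaInput(parameter_name=parameter, studies=studies)


def meta_input_from_frame(df: pd.DataFrame, parameter: str) -> MetaInput:
    """Build a MetaInput from any frame with parameter,strain,estimate,se."""
    sub = df[df["parameter"] == parameter]
    studies = tuple(
        MetaStudy(label=str(row.strain), estimate=float(row.estimate), se=float(row.se))
        for row in sub.itertuples()
    )
    return MetaInput(parameter_name=parameter, studies=studies)
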