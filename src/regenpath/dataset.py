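"""Packaged observation table of the triticale anther-culture study.

One row per regenerant (37 in total, from eight induction-medium trials A-H):
the culture conditions (Cu(II) and Ag(I) concentration in the induction
medium, days of anther culture), the CHH-context metAFLP characteristics of
the regenerant vs its donor (CHH_SV, CHH_DNMV, in %), the unit-area-normalized
FTIR integrated absorbance over 2,540-2,550 cm^-1 (GSH proxy), and the green
plant regeneration efficiency (GPRE, regenerants per 100 plated anthers).
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_study_table", "STUDY_VARIABLES", "IntegrityError"]

#: Column order used throughout the path-model analysis.
STUDY_VARIABLES = ("cu", "chh_sv", "chh_dnmv", "gsh", "gpre")

_RESOURCE = "anther_culture_trials.tsv"
_SHA256 = "68a99ec54eb89ab1de3b4d669bce6ac5c8b4882a43d8054852c2f2452088b204"

_CU_LEVELS = {0.1, 5.0, 10.0}
_AG_LEVELS = {0.0, 10.0, 60.0}
_TIME_LEVELS = {35, 42, 49}


class IntegrityError(RuntimeError):
    """Packaged data file does not match its recorded checksum."""


def load_study_table(verify: bool = True) -> pd.DataFrame:
    """Load the 37-regenerant observation table.

    Columns: ``trial`` (A-H), ``cu`` (µM), ``ag`` (µM), ``time`` (days),
    ``chh_sv`` (%), ``chh_dnmv`` (%), ``gsh`` (integrated absorbance),
    ``gpre`` (regenerants per 100 anthers).
    """
    ref = resources.files("regenpath.data").joinpath(_RESOURCE)
    raw = ref.read_bytes()
    if verify and hashlib.sha256(raw).hexdigest() != _SHA256:
        raise IntegrityError(f"checksum mismatch for packaged resource {_RESOURCE}")
    df = pd.read_csv(ref.open(), sep="\t")
    df["time"] = df["time"].astype(int)
    _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    if set(df["cu"]) - _CU_LEVELS:
        raise ValueError("Cu levels outside the design {0.1, 5, 10} µM")
    if set(df["ag"]) - _AG_LEVELS:
        raise ValueError("Ag levels outside the design {0, 10, 60} µM")
    if set(df["time"]) - _TIME_LEVELS:
        raise ValueError("culture times outside the design {35, 42, 49} days")
    num = df[list(STUDY_VARIABLES)]
    if not num.map(lambda v: isinstance(v, (int, float))).all().all() or num.isna().any().any():
        raise ValueError("non-numeric or missing observation values")
    if (df[["chh_sv", "chh_dnmv"]] < 0).any().any():
        raise ValueError("negative percentages")
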