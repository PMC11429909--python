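"""Packaged reference screening dataset.

Ships the published colony-formation screening tables for the 38-compound
panel (8 protein sites, 9 cancer cell lines plus bone marrow) as TSV
fixtures:

* bone-marrow stem-cell colony formation at 40 uM (percent of control at
  8 and 14 days, all 38 compounds),
* compound x cell-line efficacy ratios at 40 uM for the 10 compounds with
  at least one ratio below 0.5,
* efficacy ratios at 5.7 uM for the 4 compounds carried forward.

Files are integrity-checked against packaged sha256 checksums at load
time.  "-" cells mean not tested and load as missing values.
"""

from __future__ import annotations

import hashlib
import io
import json
from importlib import resources

import pandas as pd

from .analytics import EfficacyTable, site_of_compound
from .errors import ValidationError

__all__ = [
    "load_marrow_table",
    "load_efficacy_table_40uM",
    "load_efficacy_table_5p7uM",
]

def _data_dir():
    return resources.files("pocketscreen").joinpath("data")


def _read_packaged(name: str) -> bytes:
    data = _data_dir().joinpath(name).read_bytes()
    checksums = json.loads(_data_dir().joinpath("checksums.json").read_text())
    expected = checksums.get(name)
    actual = hashlib.sha256(data).hexdigest()
    if expected != actual:
        raise ValidationError(
            f"packaged table {name} failed its checksum "
            f"(expected {expected}, got {actual})"
        )
    return data


def load_marrow_table() -> pd.DataFrame:
    """Bone-marrow percent-of-control table, indexed by compound."""
    raw = _read_packaged("table1_bone_marrow.tsv")
    df = pd.read_csv(io.BytesIO(raw), sep="\t").set_index("compound")
    return df


def _load_efficacy(name: str, concentration: float) -> EfficacyTable:
    raw = _read_packaged(name)
    df = pd.read_csv(io.BytesIO(raw), sep="\t", na_values=["-"]).set_index(
        "cell_line"
    )
    # full tested roster: every compound in the marrow panel defines the
    # per-site denominators, including compounds with no active line
    roster = load_marrow_table().index
    site_of = {compound: site_of_compound(compound) for compound in roster}
    return EfficacyTable(
        concentration=concentration, ratios=df.astype(float), site_of=site_of
    )


def load_efficacy_table_40uM() -> EfficacyTable:
    """Efficacy ratios at 40 uM with the full 38-compound site roster."""
    return _load_efficacy("table2_efficacy_40uM.tsv", 40.0)


def load_efficacy_table_5p7uM() -> EfficacyTable:
    """Efficacy ratios at 5.7 uM (selected compounds)."""
    raw = _read_packaged("table4_efficacy_5p7uM.tsv")
    df = pd.read_csv(io.BytesIO(raw), sep="\t", na_values=["-"]).set_index(
        "cell_line"
    )
    return EfficacyTable(concentration=5.7, ratios=df.astype(float))
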