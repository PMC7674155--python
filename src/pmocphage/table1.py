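"""The packaged table of curated phage genomes and its summary statistics.

The fixture is a machine-readable transcription of the published summary
of manually curated phage genomes: 27 genomes from five sites, 22 of
which carry pmoC (18 of those complete). Footnote flags (fragmented
pmoC, partial pmoC, within-population partial pmoC, highly similar
genome pairs) are explicit boolean columns.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_FIXTURE_SHA256 = "b741503d85b571db4b4591b85d38dcab99f839d411b10270cd3e2ed9c77925fd"

BOOL_COLUMNS = (
    "related_pair",
    "fragmented_pmoc",
    "within_population_partial",
    "partial_pmoc",
)


def load_table1(verify: bool = True) -> pd.DataFrame:
    """Load the packaged genome table; verifies the fixture checksum."""
    ref = resources.files("pmocphage").joinpath("data/table1.csv")
    raw = ref.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ValueError(
                "table1 fixture corrupted: checksum "
                f"{digest} != expected {_FIXTURE_SHA256}"
            )
    table = pd.read_csv(
        ref.open("r"), dtype={"year": str}, keep_default_na=False
    )
    for col in BOOL_COLUMNS:
        table[col] = table[col].astype(str).map({"True": True, "False": False})
    return table


def table1_stats(table: pd.DataFrame | None = None) -> dict[str, float | int]:
    """Summary statistics over the pmoC-carrying genomes.

    pmoC rows are those with a non-empty pmoC taxonomy; "complete" follows
    the completeness column.
    """
    if table is None:
        table = load_table1()
    pmoc = table[table["pmoc_taxonomy"] != ""]
    complete = pmoc[pmoc["completeness"] == "Complete"]
    return {
        "n_genomes": int(len(table)),
        "n_pmoc_phages": int(len(pmoc)),
        "n_complete_pmoc_phages": int(len(complete)),
        "min_length_bp": int(pmoc["length_bp"].min()),
        "max_length_bp": int(pmoc["length_bp"].max()),
        "min_gc_percent": float(pmoc["gc_percent"].min()),
        "max_gc_percent": float(pmoc["gc_percent"].max()),
        "min_orfs": int(pmoc["n_orfs"].min()),
        "max_orfs": int(pmoc["n_orfs"].max()),
        "max_trnas": int(pmoc["n_trnas"].max()),
        "n_fragmented_pmoc": int(pmoc["fragmented_pmoc"].sum()),
    }
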