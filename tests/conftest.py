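import numpy as np
import pandas as pd
import pytest

from negaprocess import (
    SizingTable,
    default_config,
    example_genotype,
    example_kit,
)
from negaprocess.io import RECORD_COLUMNS


@pytest.fixture(scope="session")
def kit():
    return example_kit()


@pytest.fixture(scope="session")
def genotype(kit):
    return example_genotype(kit)


@pytest.fixture(scope="session")
def config(kit):
    return default_config(kit)


def make_table(rows, **metadata) -> SizingTable:
    """Build a SizingTable from (sample_id, dye, size, height) tuples or dicts."""
    records = []
    for row in rows:
        if isinstance(row, dict):
            rec = {
                "sample_id": row.get("sample_id", "s1"),
                "dye": row["dye"],
                "marker": row.get("marker", ""),
                "allele": row.get("allele", ""),
                "size_bp": float(row["size_bp"]),
                "height_rfu": float(row["height_rfu"]),
                "area": float(row.get("area", row["height_rfu"] * 4)),
                "data_point": int(row.get("data_point", row["size_bp"] * 10)),
            }
        else:
            sid, dye, size, height = row
            rec = {
                "sample_id": sid,
                "dye": dye,
                "marker": "",
                "allele": "",
                "size_bp": float(size),
                "height_rfu": float(height),
                "area": float(height * 4),
                "data_point": int(size * 10),
            }
        records.append(rec)
    if records:
        df = pd.DataFrame(records, columns=list(RECORD_COLUMNS))
        df["data_point"] = df["data_point"].astype(np.int64)
    else:
        from negaprocess.io import empty_records

        df = empty_records()
    return SizingTable(df, **metadata)


@pytest.fixture
def heights_table():
    """Helper that wraps plain heights of one dye into a table."""

    def _make(heights, dye="B", sample_id="neg1", **metadata):
        return make_table(
            [(sample_id, dye, 100.0 + i, h) for i, h in enumerate(heights)], **metadata
        )

    return _make
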