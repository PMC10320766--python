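import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cfscreen.annotations import CofactorRecord, table1_records


def obs_frame(rows):
    """Build an observation table from (regulator, reporter, tier, rep, call)."""
    return pd.DataFrame(
        rows, columns=["regulator", "reporter", "tier", "replicate", "call"]
    )


def full_primary(pairs_calls):
    """Primary-tier rows: {(reg, rep): [c1, c2, c3]} -> observation rows."""
    rows = []
    for (reg, rep), calls in pairs_calls.items():
        for i, c in enumerate(calls, 1):
            rows.append((reg, rep, "primary", i, c))
    return rows


@pytest.fixture
def complex_table():
    """Annotation records for the curated cofactor-complex table."""
    return table1_records()


@pytest.fixture
def annotation_tsv(tmp_path):
    """A small well-formed annotation table on disk."""
    path = tmp_path / "annotations.tsv"
    path.write_text(
        "gene_id\tname\tcategories\tcomplexes\tphenotypes\ttissues\tclone_source\n"
        "cf-a\talpha\tmethyltransferase|plant homeodomain\t\tembryonic lethal|sterile\tintestine\torfeome\n"
        "cf-b\tbeta\tremodeler\t\tslow growth\tintestine|neuron\tahringer\n"
        "cf-c\tgamma\t\tCCR4-NOT\t\t\tnone\n"
    )
    return path


def make_record(gene_id, **kw):
    defaults = dict(name=gene_id, categories=frozenset({"remodeler"}))
    defaults.update(kw)
    return CofactorRecord(gene_id=gene_id, **defaults)
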