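import pandas as pd
import pytest

from screenomics import HitCall, MutationRecord, OmicsStore


@pytest.fixture
def sum185_store():
    """Hand-built miniature store for an androgen-receptor-enriched breast
    cancer line with three amplified/mutated, overexpressed, druggable
    driver oncogenes (FGFR3, PIK3CA, BCL2L1) plus assorted non-driver genes
    exercising every predicate combination."""
    line = "SUM185"
    cna = pd.DataFrame(
        [
            (line, "BCL2L1", 1.1286),
            (line, "FGFR3", 1.1797),
            (line, "PIK3CA", 0.1),
            (line, "ERBB2", 0.0),
            (line, "ASXL1", 1.1286),
            (line, "KIF11", 0.0),
            (line, "TP53", 0.0),
        ],
        columns=["cell_line", "gene", "dna_amp"],
    )
    expression = pd.DataFrame(
        [
            (line, "BCL2L1", 1.165838415),
            (line, "FGFR3", 2.87313456),
            (line, "PIK3CA", 0.2),
            (line, "ERBB2", 0.1),
            (line, "ASXL1", 0.49973277),
            (line, "KIF11", 0.05),
            (line, "TP53", -0.9858457),
        ],
        columns=["cell_line", "gene", "expression_lfc"],
    )
    mutations = [
        MutationRecord(line, "PIK3CA", "PIK3CAp.H1047R", 1889, hotspot=True),
        MutationRecord(line, "TP53", "TP53p.Q144*", 47, hotspot=False),
    ]
    hits = {
        line: [
            HitCall("BCL2L1", 5.85, 1, True),
            HitCall("KIF11", 3.1, 2, True),
            HitCall("FGFR3", 2.75261, 3, True),
            HitCall("PIK3CA", 2.4557, 4, True),
            HitCall("ASXL1", 2.16136, 5, False),
            HitCall("TP53", 1.93278, 6, False),
            HitCall("ERBB2", 0.2, 7, False),
        ]
    }
    return OmicsStore(
        cna=cna,
        expression=expression,
        expression_dialect="vs_normal",
        mutations=mutations,
        hits=hits,
        oncogenes=frozenset({"BCL2L1", "FGFR3", "PIK3CA", "TP53", "ERBB2"}),
        drugs={
            "BCL2L1": ("Obatoclax Mesylate", "Navitoclax", "TW 37"),
            "FGFR3": ("PD173074",),
            "PIK3CA": ("ZSTK474", "PI-103", "A66", "BKM120"),
            "CDK6": ("AT-7519", "Palbociclib"),
            "KIF11": ("S-Trityl-l-cysteine", "Ispinesib Mesylate"),
        },
        proteins=[],
    )
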