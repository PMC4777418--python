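"""Bundled reference tables."""

from importlib import resources

import pandas as pd


def load_reference_gene_table() -> pd.DataFrame:
    """Published per-gene results for the up-regulated genes of a
    genome-wide cisplatin-sensitization screen in A549 lung cancer cells.

    Columns: gene symbol, microarray log2 fold-change after low-dose
    cisplatin, % survival with cisplatin, Survival Index, Potentiation,
    Gene Score, whole-genome Gene Score rank (out of 21121 genes), and a
    flag for the genes taken forward to wet-lab validation.  Used as a
    worked-example fixture for the scoring and rank-filter stages.
    """
    with resources.files("cisscreen.data").joinpath(
        "reference_gene_table.csv"
    ).open() as fh:
        return pd.read_csv(fh)


#: Number of genes in the whole-genome screen the reference ranks refer to.
REFERENCE_UNIVERSE_SIZE = 21121
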