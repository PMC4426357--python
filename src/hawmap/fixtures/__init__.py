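"""Packaged fixture tables: transcriptions of the published candidate-lesion
and complementation tables, the printed CRISPR guide/oligo sequences, and a
small synthetic brood-count example."""

from importlib import resources

import pandas as pd


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def load_variant_tables() -> pd.DataFrame:
    """The per-strain candidate-lesion rows (strain, gene, mutation,
    description, causal flag)."""
    with resources.as_file(_path("legacy_variant_tables.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment=None)


def load_complementation_results() -> pd.DataFrame:
    """Printed complementation percentages and verdicts."""
    with resources.as_file(_path("complementation_results.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_crispr_sequences() -> dict:
    """Guide and repair-oligo sequences as a name -> sequence dict."""
    from Bio import SeqIO

    with resources.as_file(_path("cdc25_2_crispr.fa")) as p:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")}


def synthetic_broods_path():
    """Path to the synthetic demonstration brood TSV."""
    return _path("broods_synthetic.tsv")
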