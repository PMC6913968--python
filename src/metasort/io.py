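"""File round-trips for the pipeline's plain-text interchange formats.

Sequences travel as FASTA (via Biopython); MOTU count tables as TSV with a
replicate-metadata sidecar CSV; hit tables as BLAST-outfmt-6-like TSV with a
slash-delimited lineage column; registers and taxon lists as CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assignment import load_hits
from .motu import MotuTable
from .taxonomy import Register, TaxonList


def read_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, sequences: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs."""
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def load_motu_table(counts_tsv: str | Path, replicates_csv: str | Path,
                    motus_csv: str | Path) -> MotuTable:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    replicates = pd.read_csv(replicates_csv, index_col=0)
    motus = pd.read_csv(motus_csv, index_col=0)
    return MotuTable(counts, replicates, motus)


def write_motu_table(table: MotuTable, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.counts.rename_axis("motu").to_csv(outdir / "motu_counts.tsv",
                                            sep="\t")
    table.replicates.rename_axis("replicate").to_csv(
        outdir / "replicates.csv")
    table.motus.rename_axis("motu").to_csv(outdir / "motus.csv")


def load_refdb_species(path: str | Path) -> frozenset[str]:
    return frozenset(pd.read_csv(path)["species"])


def load_study_dir(indir: str | Path):
    """Load the file set a simulation (or an importer) writes: register,
    reference species, MOTU table, both hit tables and the morphology list.
    Returns them in `run_pipeline` argument order."""
    indir = Path(indir)
    register = Register.from_csv(indir / "register.csv")
    refdb = load_refdb_species(indir / "refdb_species.csv")
    table = load_motu_table(indir / "motu_counts.tsv",
                            indir / "replicates.csv", indir / "motus.csv")
    wfd = load_hits(indir / "hits_wfd.tsv")
    genbank = load_hits(indir / "hits_genbank.tsv")
    morphology = TaxonList.from_csv(indir / "morphology.csv",
                                    origin="morphology")
    return table, wfd, genbank, register, morphology, refdb
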