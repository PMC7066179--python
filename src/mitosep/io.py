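"""Readers/writers for the pipeline's plain-text interchange formats.

Tables are TSV (pandas); peptides FASTA (Biopython); gene sets GMT; models
SBML L3 FBC or the JSON dialect of :mod:`.metabolic_model`; filter
configurations YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metabolic_model import MetabolicModel, read_sbml
from .sorf_filter import ClassThresholds, FilterConfig


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set collection: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path,
              description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(members)
             for name, members in gene_sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=pid, description="")
               for pid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_model(path) -> MetabolicModel:
    """Metabolic model from SBML (.xml/.sbml) or the JSON dialect (.json)."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        return MetabolicModel.from_json(p.read_text())
    return read_sbml(str(p))


def read_filter_config(path) -> FilterConfig:
    """Per-class sORF filter thresholds from a YAML mapping class -> fields."""
    raw = yaml.safe_load(Path(path).read_text())
    return FilterConfig({cls: ClassThresholds(**(fields or {}))
                         for cls, fields in raw.items()})


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_roles(path) -> pd.Series:
    """Two-column TSV (gene, role) -> gene-indexed role Series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
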