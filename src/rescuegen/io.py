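"""Readers and writers for Genepop, FASTA alignments and the package CSV dialects.

Genepop dialect: title line, one locus name per line (or comma-separated),
``Pop`` markers, then ``name , a1a2 a1a2 ...`` rows with 2- or 3-digit
allele codes; ``00``/``000`` (doubled) encodes a missing genotype.
Population names are taken from the first individual label of each block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from rescuegen.containers import (
    MISSING,
    AlignmentError,
    FormatError,
    GenotypeTable,
    HaplotypeSet,
    SiteEnvTable,
)


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _parse_allele_pair(code: str, path: str, lineno: int) -> tuple[int, int]:
    if len(code) == 4:
        digits = 2
    elif len(code) == 6:
        digits = 3
    else:
        raise FormatError(
            f"{path}:{lineno}: allele code {code!r} is not 4 or 6 digits"
        )
    try:
        a, b = int(code[:digits]), int(code[digits:])
    except ValueError:
        raise FormatError(f"{path}:{lineno}: unparseable allele code {code!r}") from None
    if (a == 0) != (b == 0):
        raise FormatError(
            f"{path}:{lineno}: half-missing genotype {code!r}"
        )
    return a, b


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a Genepop 4.x file into a :class:`GenotypeTable`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: too short to be a Genepop file")
    # locus names: lines 2.. until the first 'Pop'; a single line may carry
    # comma-separated names
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: no 'Pop' marker found")
    if not loci:
        raise FormatError(f"{path}: no locus names before first 'Pop'")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_name = ""
    pop_count = 0
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_count += 1
            pop_name = ""
            continue
        if "," not in line:
            raise FormatError(f"{path}:{lineno}: expected 'name , genotypes' row")
        name, _, geno_part = line.partition(",")
        name = name.strip()
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise FormatError(
                f"{path}:{lineno}: {len(codes)} genotype fields for "
                f"{len(loci)} loci"
            )
        if not pop_name:
            pop_name = name or f"pop{pop_count}"
        row: list[int] = []
        for code in codes:
            a, b = _parse_allele_pair(code, str(path), lineno)
            row.extend((a, b))
        ids.append(name)
        pops.append(pop_name)
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no individuals found")
    geno = np.asarray(rows, dtype=np.int32).reshape(len(rows), len(loci), 2)
    return GenotypeTable(ids, pops, loci, geno)


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "rescuegen export") -> None:
    """Write a :class:`GenotypeTable` as a 3-digit Genepop file."""
    if (table.genotypes > 999).any():
        raise FormatError("allele sizes above 999 cannot be written as 3-digit Genepop")
    path = Path(path)
    out = [title]
    out.extend(table.loci)
    last_pop: str | None = None
    for i in range(table.n_individuals):
        pop = table.populations[i]
        if pop != last_pop:
            out.append("Pop")
            last_pop = pop
        codes = " ".join(
            f"{a:03d}{b:03d}" for a, b in table.genotypes[i]
        )
        out.append(f"{table.individual_ids[i]} , {codes}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Tabular CSV dialects
# ---------------------------------------------------------------------------

def read_genotype_csv(path: str | Path) -> GenotypeTable:
    """Read the package's tabular genotype dialect.

    Columns: individual_id, population, optional site, then two columns
    per locus named ``<locus>.1`` / ``<locus>.2`` with allele sizes
    (0 = missing).
    """
    df = pd.read_csv(path)
    for col in ("individual_id", "population"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    allele_cols = [c for c in df.columns if c.endswith(".1") or c.endswith(".2")]
    loci: list[str] = []
    for c in allele_cols:
        base = c[:-2]
        if base not in loci:
            loci.append(base)
    for locus in loci:
        for suffix in (".1", ".2"):
            if locus + suffix not in df.columns:
                raise FormatError(f"{path}: locus {locus!r} lacks column {locus + suffix!r}")
    geno = np.zeros((len(df), len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        geno[:, j, 0] = df[f"{locus}.1"].to_numpy()
        geno[:, j, 1] = df[f"{locus}.2"].to_numpy()
    sites = df["site"].astype(str).tolist() if "site" in df.columns else None
    return GenotypeTable(
        df["individual_id"].astype(str).tolist(),
        df["population"].astype(str).tolist(),
        loci,
        geno,
        sites,
    )


def write_genotype_csv(table: GenotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_env_table(path: str | Path) -> SiteEnvTable:
    """Read a sites x environmental-variables CSV (site_id, population, basin, vars...)."""
    return SiteEnvTable(pd.read_csv(path))


def write_env_table(env: SiteEnvTable, path: str | Path) -> None:
    env.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(
    path: str | Path, pop_field: int = 1, sep: str = "|"
) -> HaplotypeSet:
    """Read an aligned FASTA into a :class:`HaplotypeSet`.

    The population label is parsed from the record id, which is split on
    `sep`; `pop_field` selects the 0-based field (default: second field,
    i.e. headers like ``>fish007|KingParrot``).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids, pops, seqs = [], [], []
    for rec in records:
        parts = rec.id.split(sep)
        if len(parts) <= pop_field:
            raise FormatError(
                f"{path}: header {rec.id!r} lacks population field {pop_field} "
                f"(separator {sep!r})"
            )
        ids.append(rec.id)
        pops.append(parts[pop_field])
        seqs.append(str(rec.seq))
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    return HaplotypeSet(ids, pops, seqs)


def write_fasta_alignment(haps: HaplotypeSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(haps.sequence_ids, haps.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

KNOWN_STAGES = ("synth", "stats", "ne", "simulate", "envmodel")


class RunConfig:
    """Stage configuration: stage name, paths, seed and a parameter block."""

    _KEYS = {"stage", "inputs", "out_dir", "seed", "params"}

    def __init__(
        self,
        stage: str,
        out_dir: str | Path,
        seed: int,
        inputs: dict[str, str] | None = None,
        params: dict | None = None,
    ) -> None:
        if stage not in KNOWN_STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {KNOWN_STAGES}")
        self.stage = stage
        self.out_dir = Path(out_dir)
        self.seed = int(seed)
        self.inputs = dict(inputs or {})
        self.params = dict(params or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        unknown = set(raw) - cls._KEYS
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("stage", "out_dir", "seed"):
            if key not in raw:
                raise FormatError(f"{path}: missing config key {key!r}")
        return cls(
            raw["stage"], raw["out_dir"], raw["seed"],
            raw.get("inputs"), raw.get("params"),
        )

    def echo(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "out_dir": str(self.out_dir),
                "seed": self.seed,
                "inputs": self.inputs,
                "params": self.params,
            },
            sort_keys=True,
        )
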