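"""Readers and writers for the pipeline's file formats.

Consumes the Roary ``gene_presence_absence.csv`` dialect (quoted CSV, 14
fixed metadata columns, one column per strain holding locus tags) or a
simplified binary TSV matrix; per-OG protein FASTA files whose headers are
strain identifiers; and a phenotype CSV of duplicate ELISA readings.
Emits the ranked score table and related result files.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .phenotype import CytokineReading, StrainPhenotype, summarize_duplicates

ROARY_META_COLUMNS = (
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
)


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class PresenceMatrix:
    """Gene presence/absence: OG rows by strain columns."""

    strain_ids: tuple[str, ...]
    og_ids: tuple[str, ...]
    present: np.ndarray  # bool (n_og, n_strain)
    annotations: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise FormatError("duplicate strain identifiers")
        if len(set(self.og_ids)) != len(self.og_ids):
            raise FormatError("duplicate OG identifiers")
        present = np.asarray(self.present, dtype=bool)
        if present.shape != (len(self.og_ids), len(self.strain_ids)):
            raise FormatError("presence matrix shape does not match id lists")
        object.__setattr__(self, "present", present)

    def strains_with(self, og_id: str) -> frozenset[str]:
        row = self.present[self.og_ids.index(og_id)]
        return frozenset(s for s, p in zip(self.strain_ids, row) if p)


@dataclass(frozen=True)
class OgFamily:
    """One orthologous gene group: strain -> member amino-acid sequence."""

    og_id: str
    members: Mapping[str, str]
    aligned: bool = False

    def __post_init__(self) -> None:
        if any(not seq for seq in self.members.values()):
            raise FormatError(f"empty member sequence in family {self.og_id!r}")
        if self.aligned and len({len(s) for s in self.members.values()}) > 1:
            raise FormatError(
                f"family {self.og_id!r} flagged aligned but lengths differ"
            )


def read_presence_absence(path: str | Path, dialect: str = "roary") -> PresenceMatrix:
    """Parse a presence/absence table.

    ``roary``: quoted CSV with the 14 fixed Roary metadata columns followed
    by one column per strain; a non-empty cell marks presence. ``binary``:
    TSV with a header of strain ids and rows of og_id followed by 0/1.
    """
    path = Path(path)
    if dialect == "roary":
        return _read_roary(path)
    if dialect == "binary":
        return _read_binary(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_roary(path: Path) -> PresenceMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "Gene":
        raise FormatError(f"{path}: first column header must be 'Gene'")
    n_meta = len(ROARY_META_COLUMNS)
    if len(header) <= n_meta:
        raise FormatError(f"{path}: no strain columns after the metadata block")
    strain_ids = tuple(header[n_meta:])
    og_ids: list[str] = []
    annotations: dict[str, str] = {}
    present_rows: list[list[bool]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row")
        og_ids.append(row[0])
        annotations[row[0]] = row[2]
        present_rows.append([cell.strip() != "" for cell in row[n_meta:]])
    if len(set(og_ids)) != len(og_ids):
        raise FormatError(f"{path}: duplicate OG identifier")
    return PresenceMatrix(
        strain_ids=strain_ids,
        og_ids=tuple(og_ids),
        present=np.array(present_rows, dtype=bool),
        annotations=annotations,
    )


def _read_binary(path: Path) -> PresenceMatrix:
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise FormatError(f"{path}: empty file")
    strain_ids = tuple(rows[0][1:])
    og_ids: list[str] = []
    present_rows: list[list[bool]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(rows[0]):
            raise FormatError(f"{path}:{lineno}: ragged row")
        og_ids.append(row[0])
        try:
            present_rows.append([bool(int(c)) for c in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-binary cell") from exc
    if len(set(og_ids)) != len(og_ids):
        raise FormatError(f"{path}: duplicate OG identifier")
    return PresenceMatrix(
        strain_ids=strain_ids,
        og_ids=tuple(og_ids),
        present=np.array(present_rows, dtype=bool),
    )


def write_presence_absence(
    pm: PresenceMatrix, path: str | Path, dialect: str = "roary"
) -> None:
    """Write a PresenceMatrix in either dialect (inverse of the reader)."""
    path = Path(path)
    if dialect == "roary":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
            writer.writerow(list(ROARY_META_COLUMNS) + list(pm.strain_ids))
            for i, og in enumerate(pm.og_ids):
                row = pm.present[i]
                n_iso = int(row.sum())
                annotation = (pm.annotations or {}).get(og, "")
                meta = [
                    og, "", annotation, str(n_iso), str(n_iso),
                    "1.0", "", "", "", "", "", "", "", "",
                ]
                cells = [
                    f"{strain}_{og}" if p else ""
                    for strain, p in zip(pm.strain_ids, row)
                ]
                writer.writerow(meta + cells)
    elif dialect == "binary":
        with open(path, "w") as fh:
            fh.write("og_id\t" + "\t".join(pm.strain_ids) + "\n")
            for i, og in enumerate(pm.og_ids):
                fh.write(
                    og + "\t" + "\t".join(str(int(p)) for p in pm.present[i]) + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_og_sequences(
    directory: str | Path, presence: PresenceMatrix
) -> dict[str, OgFamily]:
    """Load one ``<og_id>.faa`` FASTA per OG from a directory.

    Headers are matched to strain ids by their first whitespace-delimited
    token; records with unknown headers are skipped with a warning. If a
    strain contributes several records (paralogs) the longest is kept, ties
    resolved by the lexicographically first full header. Sequences are
    upper-cased and '*' stop characters stripped.
    """
    directory = Path(directory)
    known = set(presence.strain_ids)
    families: dict[str, OgFamily] = {}
    for og_id in presence.og_ids:
        fasta = directory / f"{og_id}.faa"
        if not fasta.exists():
            continue
        best: dict[str, tuple[int, str, str]] = {}  # strain -> (-len, header, seq)
        n_records = 0
        for rec in SeqIO.parse(str(fasta), "fasta"):
            n_records += 1
            strain = rec.description.split()[0] if rec.description else rec.id
            if strain not in known:
                warnings.warn(
                    f"{fasta.name}: header {strain!r} matches no strain id; "
                    "record skipped",
                    stacklevel=2,
                )
                continue
            seq = str(rec.seq).upper().replace("*", "")
            key = (-len(seq), rec.description)
            if strain not in best or key < best[strain][:2]:
                best[strain] = (key[0], key[1], seq)
        if n_records == 0 or not best:
            warnings.warn(f"{fasta.name}: no usable records; OG skipped", stacklevel=2)
            continue
        members = {s: v[2] for s, v in best.items()}
        aligned = len({len(s) for s in members.values()}) == 1
        families[og_id] = OgFamily(og_id=og_id, members=members, aligned=aligned)
    return families


def read_phenotypes(path: str | Path) -> list[StrainPhenotype]:
    """Parse a phenotype CSV: strain_id, species, cytokine, rep1, rep2.

    Both cytokines (IL10, IL12) are required for every strain; negative or
    missing measurements are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"strain_id", "species", "cytokine", "rep1", "rep2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df[["rep1", "rep2"]].isna().any().any():
        raise FormatError(f"{path}: missing replicate measurement")
    out: list[StrainPhenotype] = []
    for (strain, species), grp in df.groupby(["strain_id", "species"], sort=True):
        values: dict[str, CytokineReading] = {}
        for _, row in grp.iterrows():
            mean = summarize_duplicates(float(row.rep1), float(row.rep2))
            values[str(row.cytokine)] = CytokineReading(
                float(row.rep1), float(row.rep2), mean
            )
        for cy in ("IL10", "IL12"):
            if cy not in values:
                raise FormatError(
                    f"{path}: strain {strain!r} lacks a {cy} measurement row"
                )
        out.append(
            StrainPhenotype(strain_id=str(strain), species=str(species), values=values)
        )
    return out


def write_phenotypes(strains: Sequence[StrainPhenotype], path: str | Path) -> None:
    rows = [
        {
            "strain_id": s.strain_id,
            "species": s.species,
            "cytokine": cy,
            "rep1": repr(v.rep1),
            "rep2": repr(v.rep2),
        }
        for s in strains
        for cy, v in sorted(s.values.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


_SCORE_COLUMNS = (
    "og_id", "n_overall", "n_active", "n_silent", "bgss", "wgss",
    "ch_index", "seq_dist_factor", "pg_index", "pg_rank",
    "in_top_fraction", "kmeans_ch", "kmeans_rank",
)


def _fmt(x: float | None) -> str:
    if x is None:
        return "NA"
    if math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def write_score_table(scores, path: str | Path) -> None:
    """Write PG scores as a TSV, sorted by PG index descending (og_id ties
    ascending); floats at 6 significant digits."""
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to write")
    ordered = sorted(scores, key=lambda s: (-s.pg_index, s.og_id))
    ranked_ch = sorted(
        (s for s in ordered if s.kmeans_ch is not None),
        key=lambda s: (-s.kmeans_ch, s.og_id),
    )
    kmeans_rank = {s.og_id: i + 1 for i, s in enumerate(ranked_ch)}
    with open(path, "w") as fh:
        fh.write("\t".join(_SCORE_COLUMNS) + "\n")
        for rank, s in enumerate(ordered, start=1):
            fh.write(
                "\t".join(
                    [
                        s.og_id,
                        str(s.n_overall),
                        str(s.n_active),
                        str(s.n_silent),
                        _fmt(s.bgss),
                        _fmt(s.wgss),
                        _fmt(s.ch_index),
                        _fmt(s.seq_dist_factor),
                        _fmt(s.pg_index),
                        str(rank),
                        str(s.in_top_fraction),
                        _fmt(s.kmeans_ch),
                        str(kmeans_rank.get(s.og_id, "NA")),
                    ]
                )
                + "\n"
            )


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a score TSV back into a DataFrame (inf and NA preserved)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_groups_table(groups_list, path: str | Path) -> None:
    """Write classification results: species, cytokine, median, strain, group."""
    with open(path, "w") as fh:
        fh.write("species\tcytokine\tmedian\tstrain_id\tgroup\n")
        for g in groups_list:
            for strain in sorted(g.strains):
                fh.write(
                    f"{g.species}\t{g.cytokine}\t{_fmt(g.median)}\t"
                    f"{strain}\t{g.label_of(strain)}\n"
                )


def write_distance_matrix(dm, path: str | Path) -> None:
    """Labeled square TSV (header row + row labels)."""
    with open(path, "w") as fh:
        fh.write("strain_id\t" + "\t".join(dm.strain_ids) + "\n")
        for sid, row in zip(dm.strain_ids, dm.d):
            fh.write(sid + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def write_mds_coords(strain_ids, coords, path: str | Path) -> None:
    k = coords.shape[1]
    with open(path, "w") as fh:
        fh.write("strain_id\t" + "\t".join(f"dim{i+1}" for i in range(k)) + "\n")
        for sid, row in zip(strain_ids, coords):
            fh.write(sid + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
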