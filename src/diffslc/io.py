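"""Readers and writers for the pipeline's on-disk formats.

Inputs: PSI-MI MITAB 2.5 interaction files (as distributed by DIP),
tab-delimited probeset-by-sample expression matrices, probeset annotation
tables (probeset_id / uniprot_acc / ensembl_id), and plain-text essential-gene
lists (DEG / SGDP style). Outputs: provenance-stamped TSV ranking tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "InteractionRecord",
    "EssentialSet",
    "IdMap",
    "MitabParseError",
    "read_mitab",
    "write_mitab",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_essential_list",
    "build_id_map",
    "write_ranking",
    "read_ranking",
]

log = logging.getLogger(__name__)

MITAB_MIN_COLUMNS = 15


class MitabParseError(ValueError):
    """Raised when a MITAB line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class InteractionRecord:
    """One MITAB data line: a pair of interactors with taxa and cross-refs."""

    interactor_a: str
    interactor_b: str
    taxon_a: int
    taxon_b: int
    xrefs_a: tuple[tuple[str, str], ...] = ()
    xrefs_b: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.interactor_a or not self.interactor_b:
            raise ValueError("interactor identifiers must be non-empty")
        if self.taxon_a <= 0 or self.taxon_b <= 0:
            raise ValueError("taxon ids must be positive")


@dataclass
class EssentialSet:
    """Canonical essential-gene identifiers plus a synonym lookup.

    Identifiers are canonicalized by trimming whitespace and upper-casing,
    so membership tests are case-insensitive.
    """

    genes: set[str] = field(default_factory=set)
    synonym_map: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def normalize(identifier: str) -> str:
        return identifier.strip().upper()

    def canonical(self, identifier: str) -> str:
        key = self.normalize(identifier)
        return self.synonym_map.get(key, key)

    def __contains__(self, identifier: str) -> bool:
        return self.canonical(identifier) in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class IdMap:
    """Interactor -> probeset mapping with per-interactor provenance.

    ``provenance`` records how each interactor was resolved: "uniprot",
    "ensembl", or "unmapped" (kept, never silently dropped).
    """

    entries: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def get(self, interactor: str) -> str | None:
        return self.entries.get(interactor)

    @property
    def unmapped(self) -> list[str]:
        return [k for k, v in self.provenance.items() if v == "unmapped"]


def _parse_field_entries(raw: str) -> tuple[tuple[str, str], ...]:
    """Parse a pipe-separated MITAB field of db:accession entries."""
    entries = []
    for token in raw.split("|"):
        token = token.strip()
        if not token or token == "-":
            continue
        if ":" in token:
            db, acc = token.split(":", 1)
            entries.append((db.strip().lower(), acc.strip()))
        else:
            entries.append(("", token))
    return tuple(entries)


def _primary_id(raw: str) -> str:
    """Primary interactor identity: accession of the field's first entry.

    DIP files carry ``DIP-327N|refseq:...|uniprotkb:...``; identity is keyed
    on the DIP accession, cross-references are used only for mapping.
    """
    first = raw.split("|", 1)[0].strip()
    if ":" in first:
        return first.split(":", 1)[1].strip()
    return first


def _parse_taxid(raw: str) -> int | None:
    """Extract the first NCBI taxon id from a ``taxid:NNNN(name)`` field."""
    for token in raw.split("|"):
        token = token.strip()
        if token.lower().startswith("taxid:"):
            value = token[len("taxid:"):]
            value = value.split("(", 1)[0].strip()
            try:
                return int(value)
            except ValueError:
                return None
    return None


def read_mitab(path: str | Path, taxon_filter: int | None = None) -> list[InteractionRecord]:
    """Read a PSI-MI MITAB 2.5 file into interaction records.

    Accepts 15-column MITAB 2.5 and wider variants. When ``taxon_filter`` is
    given, records where either interactor's taxon differs are excluded.
    Lines whose taxon field cannot be parsed are skipped with a warning;
    self-interactions are retained here and removed at graph build.

    Raises :class:`MitabParseError` (naming the line number) when a data line
    has fewer than 15 tab-separated columns.
    """
    records: list[InteractionRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or line.lower().startswith("id interactor"):
                continue  # header/comment
            cols = line.split("\t")
            if len(cols) < MITAB_MIN_COLUMNS:
                raise MitabParseError(
                    f"line {lineno}: expected >= {MITAB_MIN_COLUMNS} columns, got {len(cols)}"
                )
            taxon_a = _parse_taxid(cols[9])
            taxon_b = _parse_taxid(cols[10])
            if taxon_a is None or taxon_b is None:
                log.warning("line %d: unparseable taxon field, record skipped", lineno)
                continue
            if taxon_filter is not None and (taxon_a != taxon_filter or taxon_b != taxon_filter):
                continue
            xrefs_a = _parse_field_entries(cols[0]) + _parse_field_entries(cols[2])
            xrefs_b = _parse_field_entries(cols[1]) + _parse_field_entries(cols[3])
            records.append(
                InteractionRecord(
                    interactor_a=_primary_id(cols[0]),
                    interactor_b=_primary_id(cols[1]),
                    taxon_a=taxon_a,
                    taxon_b=taxon_b,
                    xrefs_a=xrefs_a,
                    xrefs_b=xrefs_b,
                )
            )
    return records


MITAB_HEADER = (
    "#ID(s) interactor A\tID(s) interactor B\tAlt. ID(s) interactor A\t"
    "Alt. ID(s) interactor B\tAlias(es) interactor A\tAlias(es) interactor B\t"
    "Interaction detection method(s)\tPublication 1st author(s)\t"
    "Publication Identifier(s)\tTaxid interactor A\tTaxid interactor B\t"
    "Interaction type(s)\tSource database(s)\tInteraction identifier(s)\t"
    "Confidence value(s)"
)


def write_mitab(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write minimal valid 15-column MITAB 2.5 with ``taxid:`` fields."""

    def fmt_xrefs(primary: str, xrefs: tuple[tuple[str, str], ...]) -> tuple[str, str]:
        # primary id in column 1/2, remaining cross-refs in the alt-id column
        alt = "|".join(f"{db}:{acc}" if db else acc for db, acc in xrefs if acc != primary)
        return primary, alt or "-"

    with open(path, "w") as handle:
        handle.write(MITAB_HEADER + "\n")
        for rec in records:
            id_a, alt_a = fmt_xrefs(rec.interactor_a, rec.xrefs_a)
            id_b, alt_b = fmt_xrefs(rec.interactor_b, rec.xrefs_b)
            cols = [
                id_a, id_b, alt_a, alt_b, "-", "-", "-", "-", "-",
                f"taxid:{rec.taxon_a}", f"taxid:{rec.taxon_b}",
                "-", "-", "-", "-",
            ]
            handle.write("\t".join(cols) + "\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited probeset-by-sample expression matrix.

    First column holds probeset IDs; remaining columns are numeric samples.
    Raises on duplicate probeset rows, non-numeric cells, or < 2 samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probeset rows: {dupes}")
    if df.shape[1] < 2:
        raise ValueError(f"expression matrix needs >= 2 samples, got {df.shape[1]}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].map(lambda v: not _is_number(v))
            row = df.index[bad.values.argmax()]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return df


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="probeset_id", float_format="%.12g")


def read_essential_list(path: str | Path, synonyms: str | Path | None = None) -> EssentialSet:
    """Read a plain-text essential-gene list (one identifier per line).

    Lines starting with '#' are ignored. ``synonyms``, if given, is a
    two-column TSV (synonym <tab> canonical); synonymous identifiers collapse
    onto one canonical gene. Comparison is case-insensitive after trimming.
    """
    synonym_map: dict[str, str] = {}
    if synonyms is not None:
        syn = pd.read_csv(synonyms, sep="\t", header=None, comment="#", dtype=str)
        for alias, canonical in zip(syn[0], syn[1]):
            synonym_map[EssentialSet.normalize(alias)] = EssentialSet.normalize(canonical)
    result = EssentialSet(synonym_map=synonym_map)
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            result.genes.add(result.canonical(line))
    if not result.genes:
        log.warning("essential-gene list %s is empty", path)
    return result


def build_id_map(
    records: Iterable[InteractionRecord],
    annotations: pd.DataFrame,
    expr: pd.DataFrame,
    selector: str = "mean",
) -> IdMap:
    """Map each interactor to at most one expression probeset.

    Matching is attempted first through UniProtKB accessions, then Ensembl.
    When multiple probesets match one interactor, the probeset with the lowest
    expression across samples is chosen — a conservative rule: any of the
    candidate transcripts must have undergone at least that much transcription.
    ``selector`` picks the summary used ("mean" over samples, or "min").
    Unmatched interactors are recorded with provenance "unmapped".
    """
    cols = set(annotations.columns)
    if "uniprot_acc" not in cols and "ensembl_id" not in cols:
        raise ValueError("annotation table needs a uniprot_acc and/or ensembl_id column")
    if selector not in ("mean", "min"):
        raise ValueError(f"unknown selector {selector!r}")

    by_uniprot: dict[str, list[str]] = {}
    by_ensembl: dict[str, list[str]] = {}
    for _, row in annotations.iterrows():
        probeset = str(row["probeset_id"])
        for colname, index in (("uniprot_acc", by_uniprot), ("ensembl_id", by_ensembl)):
            if colname in cols and pd.notna(row.get(colname)) and str(row[colname]).strip() not in ("", "-"):
                index.setdefault(str(row[colname]).strip(), []).append(probeset)

    summary = expr.mean(axis=1) if selector == "mean" else expr.min(axis=1)

    def accessions(xrefs: tuple[tuple[str, str], ...], dbs: tuple[str, ...]) -> list[str]:
        return [acc for db, acc in xrefs if db in dbs]

    idmap = IdMap()
    seen: dict[str, tuple[tuple[str, str], ...]] = {}
    for rec in records:
        seen.setdefault(rec.interactor_a, rec.xrefs_a)
        seen.setdefault(rec.interactor_b, rec.xrefs_b)

    for interactor, xrefs in seen.items():
        candidates: list[str] = []
        route = "unmapped"
        for route_name, index, dbs in (
            ("uniprot", by_uniprot, ("uniprotkb", "uniprot")),
            ("ensembl", by_ensembl, ("ensembl",)),
        ):
            for acc in accessions(xrefs, dbs):
                candidates.extend(index.get(acc, ()))
            candidates = [p for p in candidates if p in summary.index]
            if candidates:
                route = route_name
                break
        if candidates:
            # deterministic: lowest summary expression, ties by probeset id
            best = min(candidates, key=lambda p: (summary.loc[p], p))
            idmap.entries[interactor] = best
        idmap.provenance[interactor] = route
    return idmap


def write_ranking(
    scores: Mapping[str, float],
    path: str | Path,
    labels: EssentialSet | None = None,
    method: str = "",
    params: Mapping[str, object] | None = None,
) -> None:
    """Write a ranking TSV: node, score, rank, and essential flag if labeled.

    Rank 1 is the highest score; ties break lexicographically by node ID.
    A commented header carries tool version and parameters for provenance.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    from diffslc import __version__

    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as handle:
        handle.write(f"# diffslc {__version__}\n")
        if method:
            handle.write(f"# method: {method}\n")
        if params:
            handle.write("# params: " + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        cols = ["node", "score", "rank"] + (["essential"] if labels is not None else [])
        handle.write("\t".join(cols) + "\n")
        for rank, (node, score) in enumerate(ordered, start=1):
            row = [node, f"{score:.15g}", str(rank)]
            if labels is not None:
                row.append("1" if node in labels else "0")
            handle.write("\t".join(row) + "\n")


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
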