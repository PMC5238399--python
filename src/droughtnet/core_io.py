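"""Parsing and I/O for gene identifiers, count tables and annotation maps.

*Brassica napus* genes are coded ``Bna<chrom>g<locus>D`` where ``<chrom>`` is a
three-character chromosome label (``A01``–``A10`` from the *B. rapa* A
subgenome, ``C01``–``C09`` from the *B. oleracea* C subgenome, or ``Ann`` /
``Cnn`` / ``Unn`` for genes with an unknown chromosome position) and
``<locus>`` is a five-digit position code. Identifiers are case-sensitive and
stored verbatim; the position code carries ordering semantics only — no
genomic-coordinate (0/1-based) meaning is claimed.

Count tables hold uniquely aligned clean-read counts for the four libraries
R, RT, S and ST together with per-gene lengths and per-library totals. The
library total counts *all* uniquely aligned reads genome-wide, so it is
carried as explicit metadata rather than inferred from column sums.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

SAMPLES = ("R", "RT", "S", "ST")

_GENE_ID_RE = re.compile(
    r"^Bna(A0[1-9]|A10|C0[1-9]|Ann|Cnn|Unn)g(\d{5})D$"
)
_PATHWAY_RE = re.compile(r"^ko\d{5}$")

_UNKNOWN_LABELS = frozenset({"Ann", "Cnn", "Unn"})


class ParseError(ValueError):
    """Raised for malformed identifiers or malformed input files."""


@dataclass(frozen=True)
class GeneLocus:
    """Decomposed *B. napus* gene identifier."""

    gene_id: str
    subgenome: str  # "A", "C" or "U"
    chromosome_label: str  # e.g. "A05", "C09", "Cnn"
    position_code: int  # integer value of the five-digit locus field
    position_unknown: bool  # True for Ann/Cnn/Unn chromosome labels


def parse_gene_id(gene_id: str) -> GeneLocus:
    """Parse a ``BnaXXXgYYYYYD`` identifier into its components.

    Raises
    ------
    ParseError
        If ``gene_id`` does not match the naming convention; the message
        names the offending string.
    """
    if not isinstance(gene_id, str) or not gene_id:
        raise ParseError(f"gene identifier must be a non-empty string, got {gene_id!r}")
    m = _GENE_ID_RE.match(gene_id)
    if m is None:
        raise ParseError(f"malformed gene identifier: {gene_id!r}")
    label, locus = m.group(1), m.group(2)
    return GeneLocus(
        gene_id=gene_id,
        subgenome=label[0],
        chromosome_label=label,
        position_code=int(locus),
        position_unknown=label in _UNKNOWN_LABELS,
    )


@dataclass
class CountTable:
    """Per-gene uniquely aligned clean-read counts for the four libraries.

    Attributes
    ----------
    counts : pandas.DataFrame
        Integer frame indexed by gene_id with columns R, RT, S, ST.
    gene_length_bases : pandas.Series
        Positive per-gene length in bases, aligned with ``counts``.
    library_total : dict
        Total uniquely aligned reads per library (N); at least the column sum.
    """

    counts: pd.DataFrame
    gene_length_bases: pd.Series
    library_total: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = self.counts.loc[:, list(SAMPLES)].astype(int)
        self.gene_length_bases = self.gene_length_bases.loc[self.counts.index].astype(int)
        self.validate()

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene identifiers: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ParseError("negative read count in count table")
        if (self.gene_length_bases <= 0).any():
            bad = self.gene_length_bases.index[self.gene_length_bases <= 0].tolist()
            raise ParseError(f"non-positive gene length for {bad}")
        for s in SAMPLES:
            if s not in self.library_total:
                raise ParseError(f"missing library total for sample {s}")
            total = int(self.library_total[s])
            if total <= 0:
                raise ParseError(f"library total for {s} must be positive")
            colsum = int(self.counts[s].sum())
            if total < colsum:
                raise ParseError(
                    f"library total for {s} ({total}) is below its column sum ({colsum})"
                )


@dataclass
class AnnotationMap:
    """Gene → KEGG pathway (``koNNNNN``) and gene → GO biological-process maps.

    ``background_gene_count`` is the whole-transcriptome background size used
    by the enrichment tests. Genes with no pathway annotation drive the
    annotation filter applied ahead of the Venn classification.
    """

    gene_to_pathways: dict[str, set[str]] = field(default_factory=dict)
    gene_to_processes: dict[str, set[str]] = field(default_factory=dict)
    background_gene_count: int = 0

    def __post_init__(self) -> None:
        if self.background_gene_count <= 0:
            raise ValueError("background_gene_count must be positive")
        for gene, pws in self.gene_to_pathways.items():
            for pw in pws:
                if not _PATHWAY_RE.match(pw):
                    raise ParseError(f"malformed pathway identifier {pw!r} for gene {gene}")

    def pathway_annotated(self, gene_id: str) -> bool:
        return bool(self.gene_to_pathways.get(gene_id))

    def unannotated_genes(self, genes: Iterable[str]) -> set[str]:
        """Genes from ``genes`` lacking any pathway annotation."""
        return {g for g in genes if not self.pathway_annotated(g)}


# ---------------------------------------------------------------------------
# count-table I/O
#
# Format: TSV with columns gene_id, length, R, RT, S, ST preceded by one
# metadata line  "#library_total R=<int> RT=<int> S=<int> ST=<int>".
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"^#library_total\s+(.*)$")


def read_count_table(path: str | Path) -> CountTable:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        m = _META_RE.match(first)
        if m is None:
            raise ParseError(f"{path}: first line must be a #library_total metadata line")
        totals: dict[str, int] = {}
        for tok in m.group(1).split():
            key, _, val = tok.partition("=")
            if key not in SAMPLES or not val:
                raise ParseError(f"{path}: bad library_total token {tok!r}")
            totals[key] = int(val)
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "length", *SAMPLES]
        if header != expected:
            unknown = [c for c in header if c not in expected]
            if unknown:
                raise ParseError(f"{path}: unknown sample label / column {unknown}")
            raise ParseError(f"{path}: header must be {expected}, got {header}")
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            gene = parts[0]
            try:
                nums = [int(p) for p in parts[1:]]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer value in {parts[1:]}") from None
            if any(n < 0 for n in nums[1:]):
                raise ParseError(f"{path}:{lineno}: negative count")
            rows.append((gene, *nums))
    if not rows:
        raise ParseError(f"{path}: no gene rows")
    frame = pd.DataFrame(rows, columns=expected).set_index("gene_id")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene identifiers {dups}")
    return CountTable(
        counts=frame[list(SAMPLES)],
        gene_length_bases=frame["length"],
        library_total=totals,
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        meta = " ".join(f"{s}={int(table.library_total[s])}" for s in SAMPLES)
        fh.write(f"#library_total {meta}\n")
        fh.write("\t".join(["gene_id", "length", *SAMPLES]) + "\n")
        for gene in table.counts.index:
            vals = [str(int(table.gene_length_bases[gene]))]
            vals += [str(int(table.counts.at[gene, s])) for s in SAMPLES]
            fh.write(gene + "\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# annotation-map I/O: two-column TSV, gene_id <TAB> term_id, one pair per line
# ---------------------------------------------------------------------------

def _read_two_column(path: str | Path, validate_pathway: bool) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(f"{path}:{lineno}: expected 'gene_id<TAB>term_id'")
            gene, term = parts
            if validate_pathway and not _PATHWAY_RE.match(term):
                raise ParseError(f"{path}:{lineno}: malformed pathway identifier {term!r}")
            mapping.setdefault(gene, set()).add(term)
    return mapping


def read_annotation_map(
    pathway_path: str | Path,
    process_path: str | Path,
    background_gene_count: int,
) -> AnnotationMap:
    return AnnotationMap(
        gene_to_pathways=_read_two_column(pathway_path, validate_pathway=True),
        gene_to_processes=_read_two_column(process_path, validate_pathway=False),
        background_gene_count=background_gene_count,
    )


def write_annotation_map(annotations: AnnotationMap, pathway_path: str | Path, process_path: str | Path) -> None:
    for mapping, path in (
        (annotations.gene_to_pathways, Path(pathway_path)),
        (annotations.gene_to_processes, Path(process_path)),
    ):
        with path.open("w") as fh:
            for gene in sorted(mapping):
                for term in sorted(mapping[gene]):
                    fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: Default thresholds for the whole pipeline. ``crucial_rules`` carries the
#: per-subgroup second-round fold-change cutoffs (see classification module).
DEFAULT_CONFIG: dict[str, float] = {
    "fdr_deg": 0.001,
    "min_abs_log2": 1.0,
    "enrich_alpha": 0.05,
    "rpkm_pseudocount": 0.001,
    "crucial_single_cutoff": 5.0,
    "crucial_rdr_pair_diff": 2.0,
    "crucial_sdr_pair_diff": 5.0,
    "crucial_cdr_pair_diff": 1.0,
    "crucial_cdr_pair_single": 3.0,
    "crucial_triple_single": 2.0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a flat-key YAML config, falling back to defaults for absent keys."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with Path(path).open() as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ParseError(f"{path}: config must be a flat mapping")
        cfg.update(user)
    return cfg


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> logging.Logger:
    """Timestamped, level-controlled logging to stderr and an optional file."""
    logger = logging.getLogger("droughtnet")
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    if logfile is not None:
        fileh = logging.FileHandler(logfile)
        fileh.setFormatter(fmt)
        logger.addHandler(fileh)
    return logger
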