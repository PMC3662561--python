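"""Readers and writers for the package's text formats.

Genotypes travel as either a simple TSV dialect or PLINK text (.ped/.map);
trees as Newick; association and annotation tables as TSV; results as a
branch TSV plus a JSON run summary.  Binary PLINK and VCF are deliberately
unsupported.

TSV genotype dialect: one row per individual, header
``individual<TAB>population<TAB><snp>=<allele>...`` where ``<allele>`` is
the counted allele of that SNP column.  Calls are 0/1/2 counted-allele
copies; ``NA``, ``.`` or an empty field is missing.  Unknown symbols are
mapped to missing with a logged count.

PLINK text: the .ped family id is used as the population label; the
counted allele of each SNP is its minor allele in the file (ties broken
alphabetically), which matches the package-wide minor-allele convention.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import PopulationTree
from .types import MISSING, GenotypeMatrix

logger = logging.getLogger("riskdrift.io")

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", ".", "-1"}


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix (``dialect`` = ``tsv`` or ``plink-text``)."""
    if dialect == "tsv":
        return _read_genotypes_tsv(Path(path))
    if dialect == "plink-text":
        return _read_genotypes_plink(Path(path))
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: no individuals (empty file)")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "individual" or header[1] != "population":
        raise ValueError(
            f"{path}: header must start with 'individual<TAB>population'"
        )
    snp_ids, counted = [], {}
    for col in header[2:]:
        snp, _, allele = col.partition("=")
        snp_ids.append(snp)
        if allele:
            counted[snp] = allele
    individuals, populations, rows = [], [], []
    unknown = 0
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        individuals.append(fields[0])
        populations.append(fields[1])
        row = np.empty(len(snp_ids), dtype=np.int8)
        for j, tok in enumerate(fields[2:]):
            tok = tok.strip()
            if tok in _MISSING_TOKENS:
                row[j] = MISSING
            elif tok in ("0", "1", "2"):
                row[j] = int(tok)
            else:
                row[j] = MISSING
                unknown += 1
        rows.append(row)
    if not individuals:
        raise ValueError(f"{path}: no individuals")
    if unknown:
        logger.warning("%s: %d unknown genotype symbol(s) mapped to missing",
                       path, unknown)
    return GenotypeMatrix(
        individuals, populations, snp_ids, np.vstack(rows), counted
    )


def _plink_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix == ".ped":
        return path, path.with_suffix(".map")
    if path.suffix == ".map":
        return path.with_suffix(".ped"), path
    return path.with_suffix(".ped"), path.with_suffix(".map")


def _read_genotypes_plink(path: Path) -> GenotypeMatrix:
    ped_path, map_path = _plink_paths(path)
    snp_ids = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{map_path}: line {lineno}: malformed map row")
            snp_ids.append(fields[1])
    with open(ped_path) as fh:
        ped_lines = [ln for ln in fh if ln.strip()]
    if not ped_lines:
        raise ValueError(f"{ped_path}: no individuals (empty file)")
    individuals, populations, allele_rows = [], [], []
    for lineno, line in enumerate(ped_lines, start=1):
        fields = line.split()
        if len(fields) != 6 + 2 * len(snp_ids):
            raise ValueError(
                f"{ped_path}: line {lineno}: expected {6 + 2 * len(snp_ids)} "
                f"fields, got {len(fields)}"
            )
        populations.append(fields[0])
        individuals.append(fields[1])
        allele_rows.append(fields[6:])
    # counted allele = minor allele per SNP (alphabetical on ties)
    calls = np.full((len(individuals), len(snp_ids)), MISSING, dtype=np.int8)
    counted = {}
    half_missing = 0
    for j, snp in enumerate(snp_ids):
        pairs = [(row[2 * j], row[2 * j + 1]) for row in allele_rows]
        tally: Counter[str] = Counter()
        for a1, a2 in pairs:
            if a1 != "0" and a2 != "0":
                tally.update((a1, a2))
        if not tally:
            counted[snp] = "0"
            continue
        if len(tally) > 2:
            raise ValueError(f"{ped_path}: SNP {snp} has >2 alleles")
        minor = min(tally.items(), key=lambda kv: (kv[1], kv[0]))[0]
        counted[snp] = minor
        for i, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                if (a1 == "0") != (a2 == "0"):
                    half_missing += 1
                continue
            calls[i, j] = (a1 == minor) + (a2 == minor)
    if half_missing:
        logger.warning(
            "%s: %d half-missing genotype(s) mapped to missing",
            ped_path, half_missing,
        )
    return GenotypeMatrix(individuals, populations, snp_ids, calls, counted)


def write_genotypes(
    genotypes: GenotypeMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a genotype matrix in the given dialect."""
    path = Path(path)
    if dialect == "tsv":
        header = ["individual", "population"] + [
            f"{s}={genotypes.counted_allele[s]}" if s in genotypes.counted_allele
            else s
            for s in genotypes.snp_ids
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i, ind in enumerate(genotypes.individuals):
                row = [ind, genotypes.populations[i]]
                for v in genotypes.calls[i]:
                    row.append("NA" if v == MISSING else str(int(v)))
                fh.write("\t".join(row) + "\n")
    elif dialect == "plink-text":
        ped_path, map_path = _plink_paths(path)
        with open(map_path, "w") as fh:
            for j, snp in enumerate(genotypes.snp_ids):
                fh.write(f"1\t{snp}\t0\t{j + 1}\n")
        # counted allele vs an arbitrary fixed other symbol
        others = {
            s: "T" if genotypes.counted_allele.get(s, "A") != "T" else "G"
            for s in genotypes.snp_ids
        }
        with open(ped_path, "w") as fh:
            for i, ind in enumerate(genotypes.individuals):
                fields = [genotypes.populations[i], ind, "0", "0", "0", "-9"]
                for j, snp in enumerate(genotypes.snp_ids):
                    v = genotypes.calls[i, j]
                    m = genotypes.counted_allele.get(snp, "A")
                    o = others[snp]
                    if v == MISSING:
                        fields += ["0", "0"]
                    else:
                        fields += [m] * int(v) + [o] * (2 - int(v))
                fh.write(" ".join(fields) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def read_tree(
    path: str | Path,
    genotype_populations: set[str] | None = None,
    allow_resolve: bool = False,
) -> PopulationTree:
    """Read a rooted Newick tree, optionally checking its leaves."""
    tree = PopulationTree.from_newick(str(path), allow_resolve=allow_resolve)
    if genotype_populations is not None:
        tree.validate_populations(genotype_populations)
    return tree


def write_tree(tree: PopulationTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ----------------------------------------------------------------------
# tables
# ----------------------------------------------------------------------

def read_associations(path: str | Path) -> pd.DataFrame:
    """Read an association table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "disease", "study_population", "sample_size",
                "p_value", "risk_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {', '.join(sorted(missing))}")
    return df


def write_associations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a genome-wide SNP annotation table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "global_maf", "functional_category",
                "phenotype_associated"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns: {', '.join(sorted(missing))}")
    df["phenotype_associated"] = df["phenotype_associated"].astype(bool)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["phenotype_associated"] = out["phenotype_associated"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

def write_results(
    branch_table: pd.DataFrame,
    run_summary: dict,
    out_prefix: str | Path,
    events: dict | None = None,
) -> list[Path]:
    """Write a branch-result TSV plus a JSON run summary.

    ``out_prefix`` is extended with ``.branches.tsv``, ``.summary.json``
    and, when event inference was run, ``.events.json``.  Output is
    deterministic: same results, byte-identical files.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    tsv = out_prefix.with_suffix(out_prefix.suffix + ".branches.tsv")
    table = branch_table.reset_index()
    table.to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    paths.append(tsv)
    js = out_prefix.with_suffix(out_prefix.suffix + ".summary.json")
    js.write_text(json.dumps(run_summary, indent=2, sort_keys=True) + "\n")
    paths.append(js)
    if events is not None:
        ev = out_prefix.with_suffix(out_prefix.suffix + ".events.json")
        ev.write_text(json.dumps(events, indent=2, sort_keys=True) + "\n")
        paths.append(ev)
    return paths


def read_results(out_prefix: str | Path) -> tuple[pd.DataFrame, dict]:
    """Round-trip reader for :func:`write_results` output."""
    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_suffix(out_prefix.suffix + ".branches.tsv")
    js = out_prefix.with_suffix(out_prefix.suffix + ".summary.json")
    table = pd.read_csv(tsv, sep="\t").set_index("branch")
    summary = json.loads(js.read_text())
    return table, summary
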