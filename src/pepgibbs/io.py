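"""Readers and writers for every file the tool touches.

All outputs are plain tab-separated text.  The bundle of a scan consists of
per-cluster-count clustering files, frequency/PSSM matrices for the best
solution of each count, a KLD report (the data behind the stacked barplot)
and a JSON run report.  Formats are documented in docs/formats.md.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import AMINO_ACIDS
from .core import TRASH, Peptide, parse_indel, CorePlacement
from .sampler import ScanResult, Solution

CLUSTERING_COLUMNS = ["group", "sequence", "core", "offset", "indel",
                      "score", "label"]


# ---------------------------------------------------------------------------
# input

def read_peptides(path, fmt: str = "auto") -> list[Peptide]:
    """Read a peptide list from tabular text or FASTA.

    Tabular: one peptide per line, optional second whitespace-separated
    column used as label; blank lines and '#' comments ignored.  FASTA:
    record ids become labels.  ``fmt="auto"`` sniffs a leading '>'.
    """
    path = Path(path)
    text = path.read_text()
    if fmt == "auto":
        stripped = text.lstrip()
        fmt = "fasta" if stripped.startswith(">") else "tabular"
    peptides: list[Peptide] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(path, "fasta"):
            peptides.append(Peptide(len(peptides), str(rec.seq).upper(),
                                    rec.id or None))
    elif fmt == "tabular":
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) > 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'sequence [label]', "
                    f"got {len(parts)} columns")
            label = parts[1] if len(parts) == 2 else None
            peptides.append(Peptide(len(peptides), parts[0].upper(), label))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not peptides:
        raise ValueError(f"{path}: no peptides found")
    return peptides


# ---------------------------------------------------------------------------
# clustering file

def write_clustering(solution: Solution, path) -> None:
    """One row per peptide, in input order: group, sequence, aligned core,
    offset, indel description, score (bits) and input label.

    Trash rows show group "Trash" with core "-" and score "NA".  In core
    strings, insertion gaps appear as '-' and bulged (deleted) residues as
    lowercase letters between the motif columns.
    """
    L = solution.config.motif_length
    by_index = {p.index: p for p in solution.peptides}
    rows = []
    for a in sorted(solution.assignments, key=lambda a: a.peptide_index):
        pep = by_index[a.peptide_index]
        label = pep.label if pep.label else "-"
        if a.in_trash:
            rows.append(["Trash", pep.sequence, "-", "-", "-", "NA", label])
        else:
            rows.append([str(a.group + 1), pep.sequence,
                         a.placement.core_string(pep.sequence, L),
                         str(a.placement.offset), a.placement.describe(),
                         f"{a.score:.4f}", label])
    with open(path, "w") as fh:
        fh.write("\t".join(CLUSTERING_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_clustering(path) -> pd.DataFrame:
    """Parse a clustering file back into a typed DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != CLUSTERING_COLUMNS:
        raise ValueError(f"{path}: not a clustering file")
    return df


def placements_from_clustering(df: pd.DataFrame
                               ) -> list[tuple[str, int, Optional[CorePlacement]]]:
    """(sequence, group, placement) triples; group -1 for trash rows."""
    out = []
    for _, row in df.iterrows():
        if row["group"] == "Trash":
            out.append((row["sequence"], TRASH, None))
            continue
        kind, pos, ln = parse_indel(row["indel"])
        out.append((row["sequence"], int(row["group"]) - 1,
                    CorePlacement(int(row["offset"]), kind, pos, ln)))
    return out


# ---------------------------------------------------------------------------
# matrices

def _write_matrix(values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(AMINO_ACIDS) + "\n")
        for row in values:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix(path) -> np.ndarray:
    """Read a frequency or PSSM matrix written by :func:`write_matrices`."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(AMINO_ACIDS):
        raise ValueError(f"{path}: unexpected residue header")
    return df.to_numpy(dtype=float)


def write_matrices(solution: Solution, directory) -> list[Path]:
    """Per cluster: gibbs.<k>of<K>.freq.mat and .pssm.mat (K = de-facto count)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    K = solution.n_clusters
    paths = []
    for g in sorted(solution.models):
        model = solution.models[g]
        fp = directory / f"gibbs.{g + 1}of{K}.freq.mat"
        pp = directory / f"gibbs.{g + 1}of{K}.pssm.mat"
        _write_matrix(model.freq.values, fp)
        _write_matrix(model.pssm.values, pp)
        paths.extend([fp, pp])
    return paths


# ---------------------------------------------------------------------------
# KLD report

def write_kld_report(scan: ScanResult, path, plot_path=None) -> None:
    """Tabular form of the KLD-vs-cluster-count barplot.

    One row per cluster count: total KLD of the best restart, per-cluster
    KLD contributions and per-cluster sizes (comma-separated, the stacked
    blocks of the bar).  A final line names the suggested count.
    """
    with open(path, "w") as fh:
        fh.write("g\tkld_total\tkld_per_cluster\tcluster_sizes\n")
        for g in sorted(scan.best):
            sol = scan.best[g]
            per = ",".join(f"{sol.kld_per_cluster[k]:.6f}"
                           for k in sorted(sol.kld_per_cluster))
            sizes = sol.cluster_sizes()
            sz = ",".join(str(sizes[k]) for k in sorted(sizes))
            fh.write(f"{g}\t{sol.kld_total:.6f}\t{per}\t{sz}\n")
        fh.write(f"suggested_g\t{scan.suggested_g}\n")
    if plot_path is not None:
        _plot_kld(scan, plot_path)


def _plot_kld(scan: ScanResult, plot_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    gs = sorted(scan.best)
    fig, ax = plt.subplots(figsize=(4, 3))
    for g in gs:
        sol = scan.best[g]
        bottom = 0.0
        for k in sorted(sol.kld_per_cluster):
            h = sol.kld_per_cluster[k]
            ax.bar(g, h, bottom=bottom, color="black", edgecolor="white",
                   linewidth=0.8)
            bottom += h
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("KLD (bits)")
    ax.set_xticks(gs)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# run report / bundle

def write_run_report(scan: ScanResult, paths: Sequence[Path], path,
                     n_input: int, n_dropped: int) -> None:
    """JSON summary: run id, config echo, KLD table, suggestion, file list.

    File paths are recorded relative to the report's directory, so the
    bundle is byte-identical wherever it is written.
    """
    cfg = scan.config
    base = Path(path).parent
    paths = [Path(p).relative_to(base) if Path(p).is_relative_to(base)
             else Path(p) for p in paths]
    report = {
        "run_id": cfg.run_id,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "n_input_peptides": n_input,
        "n_dropped_peptides": n_dropped,
        "kld_by_cluster_count": {str(g): scan.best[g].kld_total
                                 for g in sorted(scan.best)},
        "suggested_g": scan.suggested_g,
        "files": [str(p) for p in paths],
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_bundle(scan: ScanResult, outdir, n_input: int, n_dropped: int,
                 plot: bool = False) -> dict[str, object]:
    """Write the full output bundle for a scan; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for g in sorted(scan.best):
        sol = scan.best[g]
        cpath = outdir / f"clustering.{g}g.tsv"
        write_clustering(sol, cpath)
        paths.append(cpath)
        mdir = outdir / f"matrices.{g}g"
        paths.extend(write_matrices(sol, mdir))
    kld_path = outdir / "kld.tsv"
    plot_path = outdir / "kld.png" if plot else None
    write_kld_report(scan, kld_path, plot_path)
    paths.append(kld_path)
    report_path = outdir / "report.json"
    write_run_report(scan, paths, report_path, n_input, n_dropped)
    paths.append(report_path)
    return {"paths": paths, "kld": kld_path, "report": report_path}
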