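"""Domain types: peptides, gapped core placements, assignments and run config.

A *core placement* maps a peptide onto the L motif positions of its cluster.
Three geometries exist:

``none``
    an ungapped window of L consecutive residues starting at ``offset``;
``insertion``
    a peptide shorter than the motif spans all L positions by leaving
    ``indel_len`` contiguous motif positions empty (scored as gaps) starting
    at motif position ``indel_pos`` — models ligands with a short binding
    core;
``deletion``
    a peptide longer than the motif bulges ``indel_len`` contiguous residues
    out of the core; the bulge starts at within-core peptide index
    ``indel_pos`` and must be strictly interior to the consumed window —
    models ligands with an extended binding core.

A terminal deletion would be indistinguishable from a shifted ungapped
window, so it is excluded; terminal insertion gaps are legal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional

import numpy as np

from .alphabet import is_valid_sequence

#: Group id of the trash cluster in assignments.
TRASH = -1

IndelKind = Literal["none", "insertion", "deletion"]
_KIND_RANK = {"none": 0, "insertion": 1, "deletion": 2}


class ConfigError(ValueError):
    """A run-configuration field violates its constraints."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class Peptide:
    """One input sequence with a stable index and optional label."""

    index: int
    sequence: str
    label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class CorePlacement:
    """Mapping of a peptide onto L motif positions, possibly with one indel."""

    offset: int
    indel_kind: IndelKind = "none"
    indel_pos: Optional[int] = None
    indel_len: Optional[int] = None

    def consumed(self, motif_length: int) -> int:
        """Number of peptide residues covered by the core window."""
        if self.indel_kind == "insertion":
            return motif_length - self.indel_len
        if self.indel_kind == "deletion":
            return motif_length + self.indel_len
        return motif_length

    def sort_key(self) -> tuple:
        return (
            self.offset,
            _KIND_RANK[self.indel_kind],
            -1 if self.indel_pos is None else self.indel_pos,
            0 if self.indel_len is None else self.indel_len,
        )

    def is_legal(self, peptide_length: int, motif_length: int,
                 max_insertion_length: int, max_deletion_length: int) -> bool:
        L = motif_length
        if self.offset < 0:
            return False
        if self.indel_kind == "none":
            if self.indel_pos is not None or self.indel_len is not None:
                return False
            return self.offset + L <= peptide_length
        if self.indel_pos is None or self.indel_len is None:
            return False
        if self.indel_kind == "insertion":
            if not (1 <= self.indel_len <= max_insertion_length):
                return False
            if not (0 <= self.indel_pos and self.indel_pos + self.indel_len <= L):
                return False
            return self.offset + (L - self.indel_len) <= peptide_length
        if self.indel_kind == "deletion":
            if not (1 <= self.indel_len <= max_deletion_length):
                return False
            consumed = L + self.indel_len
            # bulge strictly interior to the consumed window
            if not (1 <= self.indel_pos and self.indel_pos + self.indel_len <= consumed - 1):
                return False
            return self.offset + consumed <= peptide_length
        return False

    def peptide_positions(self, motif_length: int) -> np.ndarray:
        """Peptide index occupying each motif position, -1 for insertion gaps."""
        L = motif_length
        pos = np.empty(L, dtype=np.int64)
        if self.indel_kind == "none":
            pos[:] = self.offset + np.arange(L)
        elif self.indel_kind == "insertion":
            j, d = self.indel_pos, self.indel_len
            pos[:j] = self.offset + np.arange(j)
            pos[j:j + d] = -1
            pos[j + d:] = self.offset + np.arange(j, L - d)
        else:  # deletion: skip indel_len residues at within-core index indel_pos
            j, d = self.indel_pos, self.indel_len
            pos[:j] = self.offset + np.arange(j)
            pos[j:] = self.offset + d + np.arange(j, L)
        return pos

    def deleted_positions(self, motif_length: int) -> np.ndarray:
        """Peptide indices bulged out of the core (empty unless deletion)."""
        if self.indel_kind != "deletion":
            return np.empty(0, dtype=np.int64)
        start = self.offset + self.indel_pos
        return start + np.arange(self.indel_len)

    def core_string(self, sequence: str, motif_length: int) -> str:
        """Display string of the consumed window.

        Motif columns are uppercase, insertion gaps are '-', bulged
        (deleted) residues appear lowercase between the motif columns.
        """
        seq = sequence.upper()
        if self.indel_kind == "insertion":
            j, d = self.indel_pos, self.indel_len
            w = seq[self.offset:self.offset + motif_length - d]
            return w[:j] + "-" * d + w[j:]
        if self.indel_kind == "deletion":
            j, d = self.indel_pos, self.indel_len
            w = seq[self.offset:self.offset + motif_length + d]
            return w[:j] + w[j:j + d].lower() + w[j + d:]
        return seq[self.offset:self.offset + motif_length]

    def describe(self) -> str:
        """Compact text form of the indel ('-' when ungapped)."""
        if self.indel_kind == "none":
            return "-"
        tag = "ins" if self.indel_kind == "insertion" else "del"
        return f"{tag}@{self.indel_pos}:{self.indel_len}"


def parse_indel(text: str) -> tuple[IndelKind, Optional[int], Optional[int]]:
    """Inverse of :meth:`CorePlacement.describe`."""
    if text == "-":
        return "none", None, None
    tag, rest = text.split("@")
    pos, length = rest.split(":")
    kind: IndelKind = "insertion" if tag == "ins" else "deletion"
    return kind, int(pos), int(length)


@dataclass(frozen=True)
class Assignment:
    """Current home of one peptide: a cluster with a placed core, or trash."""

    peptide_index: int
    group: int
    placement: Optional[CorePlacement] = None
    score: Optional[float] = None

    @property
    def in_trash(self) -> bool:
        return self.group == TRASH


@dataclass
class Config:
    """Run configuration mirroring every user-facing option.

    Scores, thresholds and KLD are all in bits (log base 2).
    """

    motif_length: int = 9
    cluster_range: tuple[int, int] = (1, 6)
    lam: float = 0.8           # penalty weight on similarity to other clusters
    sigma: float = 0.5         # bits credited per doubling of cluster size
    num_seeds: int = 5
    T_initial: float = 1.5
    num_T_steps: int = 20
    iterations_per_T: int | str = "auto"   # "auto" = one sweep per peptide
    indel_interval: int = 10
    max_insertion_length: int = 0
    max_deletion_length: int = 0
    use_trash: bool = False
    trash_threshold: float = 2.0
    clustering_move_every_iteration: bool = False
    background_model: str = "flat"         # "flat" | "data"
    beta: float = 50.0                     # pseudocount prior weight
    pseudocount_prior: str = "background"  # "background" | "blosum62"
    rng_seed: int = 1
    run_id: Optional[str] = None
    T_final: float = 1e-4
    suggestion_rtol: float = 0.01   # KLD ties within this pick the smaller g
    debug_checks: bool = False

    @property
    def indels_enabled(self) -> bool:
        return self.max_insertion_length > 0 or self.max_deletion_length > 0

    def min_peptide_length(self) -> int:
        return max(1, self.motif_length - self.max_insertion_length)

    def resolve_iterations(self, n_peptides: int) -> int:
        if self.iterations_per_T == "auto":
            return n_peptides
        return int(self.iterations_per_T)


def preset(name: str) -> Config:
    """Recommended parameter bundles for common problems.

    ``mhc1-ligands``: length-9 motif with up to 2 deletions / 1 insertion,
    trash cluster at 2 bits, clustering move at every iteration — suited to
    nearly aligned MHC class I eluted-ligand data of length 8-13.

    ``mhc2-ligands``: length-9 motif, no indels (class II grooves are open,
    cores shift freely instead), no trash.
    """
    if name == "mhc1-ligands":
        return Config(motif_length=9, max_deletion_length=2,
                      max_insertion_length=1, use_trash=True,
                      trash_threshold=2.0,
                      clustering_move_every_iteration=True)
    if name == "mhc2-ligands":
        return Config(motif_length=9, max_insertion_length=0,
                      max_deletion_length=0, use_trash=False,
                      clustering_move_every_iteration=False)
    raise ConfigError("preset", f"unknown preset {name!r}")


def validate_config(raw: Config) -> Config:
    """Check every field constraint; return the (normalized) config.

    Raises :class:`ConfigError` naming the offending field.
    """
    c = raw
    if c.motif_length < 1:
        raise ConfigError("motif_length", "must be >= 1")
    g_min, g_max = c.cluster_range
    if not (1 <= g_min <= g_max):
        raise ConfigError("cluster_range", f"empty or invalid interval [{g_min}, {g_max}]")
    for name in ("lam", "sigma", "beta"):
        v = getattr(c, name)
        if not np.isfinite(v) or v < 0:
            raise ConfigError(name, "must be finite and >= 0")
    if not (np.isfinite(c.T_initial) and c.T_initial > 0):
        raise ConfigError("T_initial", "must be > 0")
    if not (np.isfinite(c.T_final) and 0 < c.T_final <= c.T_initial):
        raise ConfigError("T_final", "must satisfy 0 < T_final <= T_initial")
    if c.num_T_steps < 1:
        raise ConfigError("num_T_steps", "must be >= 1")
    if c.num_seeds < 1:
        raise ConfigError("num_seeds", "must be >= 1")
    if c.iterations_per_T != "auto":
        try:
            it = int(c.iterations_per_T)
        except (TypeError, ValueError):
            raise ConfigError("iterations_per_T", "must be 'auto' or an integer >= 0")
        if it < 0:
            raise ConfigError("iterations_per_T", "must be 'auto' or an integer >= 0")
        c = replace(c, iterations_per_T=it)
    if c.indel_interval < 1:
        raise ConfigError("indel_interval", "must be >= 1")
    if c.max_insertion_length < 0:
        raise ConfigError("max_insertion_length", "must be >= 0")
    if c.max_deletion_length < 0:
        raise ConfigError("max_deletion_length", "must be >= 0")
    if c.max_insertion_length >= c.motif_length:
        raise ConfigError("max_insertion_length", "must be < motif_length")
    if not np.isfinite(c.trash_threshold):
        raise ConfigError("trash_threshold", "must be finite")
    if c.background_model not in ("flat", "data"):
        raise ConfigError("background_model", "must be 'flat' or 'data'")
    if c.pseudocount_prior not in ("background", "blosum62"):
        raise ConfigError("pseudocount_prior", "must be 'background' or 'blosum62'")
    return c


@dataclass(frozen=True)
class DroppedPeptide:
    peptide: Peptide
    reason: str   # "too_short" | "bad_alphabet"


def filter_peptides(peptides: Iterable[Peptide], config: Config
                    ) -> tuple[list[Peptide], list[DroppedPeptide]]:
    """Split input into placeable peptides and annotated rejects.

    A peptide is kept iff its (uppercased) sequence is over the 20-letter
    alphabet and long enough to admit at least one legal core placement,
    i.e. length >= motif_length - max_insertion_length.  Duplicates are
    retained: repeated ligands are signal, deduplication is the user's call.
    Idempotent: filtering the kept list again drops nothing.
    """
    kept: list[Peptide] = []
    dropped: list[DroppedPeptide] = []
    min_len = config.min_peptide_length()
    for p in peptides:
        seq = p.sequence.upper()
        if not is_valid_sequence(seq):
            dropped.append(DroppedPeptide(p, "bad_alphabet"))
        elif len(seq) < min_len:
            dropped.append(DroppedPeptide(p, "too_short"))
        else:
            kept.append(p if p.sequence == seq else Peptide(p.index, seq, p.label))
    return kept, dropped
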