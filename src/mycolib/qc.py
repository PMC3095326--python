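"""Sequence-authenticity rules for cloned ITS fragments.

Three screens are applied to raw clone libraries before clustering:

1. *Region-boundary detection* — the conserved 5.8S core is located in each
   clone so the variable ITS1 (prefix) and ITS2 (suffix) can be examined
   separately.
2. *Chimera screening* — a clone observed identically in two or more root
   systems is authentic by definition.  A dataset singleton is chimaeric when
   its ITS1 and ITS2 best-match references of *different genera* (with both
   region matches above a minimum identity), the signature of a PCR template
   switch.
3. *PCR-error collapse* — within a root system, a singleton sequence that is
   identical to a more abundant sequence apart from one or two substitutions
   is treated as a PCR artefact of that sequence and merged into it; when
   exactly two clones differ at 1-2 positions, the genotype is recorded as
   their IUPAC consensus (e.g. 'Y' for C/T).  Three or more unique
   substitutions are accepted as genuine variation.

Length-differing sequences are never collapsed (the rule concerns point
mutations), merges never chain (distances are always taken to the merge
target's original sequence), and the procedure is deterministic: candidates
are ranked by clone abundance with lexicographic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import IUPACData

from .align import hamming_distance
from .reference import ReferenceDB

IUPAC_CODES = set(IUPACData.ambiguous_dna_letters.upper())

# two-or-more-base set -> ambiguity code, e.g. frozenset('GT') -> 'K'
_AMBIGUITY = {
    frozenset(bases): code
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if len(bases) > 1
}
_EXPAND = {code: set(bases) for code, bases in IUPACData.ambiguous_dna_values.items()}

STATUS_AUTHENTIC = "authentic"
STATUS_CHIMERIC = "chimaeric"
STATUS_CONSENSUS = "consensus_member"


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced cloned ITS fragment with its sample-hierarchy address."""

    id: str
    sequence: str
    root_system: str
    sub_locality: str
    main_locality: str
    region_bounds: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"clone {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - IUPAC_CODES
        if bad:
            raise ValueError(f"clone {self.id}: non-IUPAC characters {sorted(bad)}")
        if self.region_bounds is not None:
            a, b = self.region_bounds
            if not 0 < a < b <= len(self.sequence):
                raise ValueError(
                    f"clone {self.id}: region bounds ({a}, {b}) invalid for "
                    f"length {len(self.sequence)}"
                )


def iupac_consensus(a: str, b: str) -> str:
    """Per-position IUPAC consensus of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("consensus requires equal-length sequences")
    out = []
    for x, y in zip(a, b):
        if x == y:
            out.append(x)
        else:
            union = frozenset(_EXPAND[x] | _EXPAND[y])
            out.append(_AMBIGUITY[union])
    return "".join(out)


def detect_region_bounds(
    record: CloneRecord | str,
    reference_5p8s_profile: str,
    min_identity: float = 0.9,
) -> tuple[int, int] | None:
    """Locate the conserved 5.8S core in a clone by best sliding-window match.

    Returns 0-based half-open (ITS1 end, 5.8S end) offsets, or ``None`` when
    no window reaches ``min_identity`` (the clone is then "unsplittable" and
    is excluded from the chimera screen but otherwise retained).  Ties go to
    the leftmost window.
    """
    seq = record.sequence if isinstance(record, CloneRecord) else record
    w = len(reference_5p8s_profile)
    if w == 0:
        raise ValueError("empty 5.8S profile")
    if len(seq) < w:
        return None
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    prof = np.frombuffer(reference_5p8s_profile.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    matches = (windows == prof).sum(axis=1)
    best = int(np.argmax(matches))
    if matches[best] / w < min_identity:
        return None
    return best, best + w


def screen_chimeras(
    records: Sequence[CloneRecord],
    reference_db: ReferenceDB,
    min_region_identity: float = 0.80,
    profile: str | None = None,
) -> pd.DataFrame:
    """Flag chimaeric clones by split-marker taxonomic consistency.

    A clone is chimaeric iff (a) its exact sequence is observed in fewer than
    two distinct root systems (replicated sequences auto-pass), and (b) the
    best reference matches of its ITS1 and ITS2 disagree at genus level, with
    both region identities at least ``min_region_identity``.  A region match
    below that floor is a "no call" and the clone passes (insufficient
    evidence).  Returns one row per clone: is_chimera, the two genus calls
    and identities, and a note for auto-passed / unsplittable clones.
    """
    if len(reference_db) == 0:
        raise ValueError("reference database is empty")
    if profile is None:
        profile = reference_db.conserved_profile()
    rs_per_seq: dict[str, set[str]] = {}
    for r in records:
        rs_per_seq.setdefault(r.sequence, set()).add(r.root_system)

    rows = []
    for r in records:
        row = {
            "clone_id": r.id,
            "is_chimera": False,
            "its1_genus": "",
            "its2_genus": "",
            "its1_identity": np.nan,
            "its2_identity": np.nan,
            "note": "",
        }
        if len(rs_per_seq[r.sequence]) >= 2:
            row["note"] = "replicated_across_root_systems"
            rows.append(row)
            continue
        bounds = r.region_bounds or detect_region_bounds(r, profile)
        if bounds is None:
            row["note"] = "unsplittable"
            rows.append(row)
            continue
        its1, its2 = r.sequence[: bounds[0]], r.sequence[bounds[1] :]
        if not its1 or not its2:
            row["note"] = "unsplittable"
            rows.append(row)
            continue
        ref1, id1 = reference_db.best_match(its1, "its1")
        ref2, id2 = reference_db.best_match(its2, "its2")
        row["its1_genus"], row["its2_genus"] = ref1["genus"], ref2["genus"]
        row["its1_identity"], row["its2_identity"] = id1, id2
        if id1 < min_region_identity or id2 < min_region_identity:
            row["note"] = "no_call_low_identity"
        elif ref1["genus"] != ref2["genus"]:
            row["is_chimera"] = True
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class _Genotype:
    """Working genotype during within-root-system collapse."""

    sequence: str  # current genotype sequence (may gain ambiguity codes)
    anchor: str  # original sequence distances are measured against
    count: int  # original clone count (merge-priority key)
    members: list[str]
    consensus: bool = False


def collapse_pcr_errors(
    records: Sequence[CloneRecord], max_diffs: int = 2
) -> tuple[list[_Genotype], pd.DataFrame]:
    """Collapse putative PCR point errors within one root system.

    Exact duplicates are pooled first.  Singletons are then processed in
    deterministic order (lexicographic by sequence) and merged into the most
    abundant equal-length sequence within ``max_diffs`` substitutions;
    between two singletons the merged genotype is the IUPAC consensus.
    Merges never chain.  Returns the surviving genotypes and a per-clone
    status table (clone_id, status, target_genotype index, n_diffs).
    """
    if not records:
        return [], pd.DataFrame(
            columns=["clone_id", "status", "target_sequence", "n_diffs"]
        )
    root_systems = {r.root_system for r in records}
    if len(root_systems) > 1:
        raise ValueError("collapse operates within a single root system")

    groups: dict[str, list[str]] = {}
    for r in records:
        groups.setdefault(r.sequence, []).append(r.id)
    genotypes = [
        _Genotype(seq, seq, len(ids), list(ids)) for seq, ids in groups.items()
    ]
    genotypes.sort(key=lambda g: (-g.count, g.sequence))

    merged_into: dict[int, tuple[int, int, str]] = {}  # idx -> (target, diffs, kind)
    singleton_idx = [i for i, g in enumerate(genotypes) if g.count == 1]
    for i in singleton_idx:
        if i in merged_into:
            continue
        s = genotypes[i]
        if len(s.members) > 1:
            # this lone clone already absorbed another one; merging it
            # onward would chain beyond max_diffs
            continue
        best: tuple[int, int, str] | None = None  # (-count, diffs ... ) key below
        best_key = None
        for j, g in enumerate(genotypes):
            if j == i or j in merged_into:
                continue
            if len(g.anchor) != len(s.anchor):
                continue
            d = hamming_distance(s.anchor, g.anchor)
            if 0 < d <= max_diffs:
                key = (-g.count, g.sequence)
                if best_key is None or key < best_key:
                    best_key, best = key, (j, d, g.sequence)
        if best is None:
            continue
        j, d, _ = best
        target = genotypes[j]
        if len(target.members) >= 2:
            target.members.extend(s.members)
            merged_into[i] = (j, d, "collapsed")
        else:
            # two lone clones differing at 1-2 positions: IUPAC consensus
            target.sequence = iupac_consensus(target.anchor, s.anchor)
            target.members.extend(s.members)
            target.consensus = True
            merged_into[i] = (j, d, STATUS_CONSENSUS)

    surviving = [g for i, g in enumerate(genotypes) if i not in merged_into]
    rows = []
    for i, g in enumerate(genotypes):
        if i in merged_into:
            j, d, status = merged_into[i]
            for cid in groups[g.anchor]:
                rows.append(
                    {
                        "clone_id": cid,
                        "status": status,
                        "target_sequence": genotypes[j].sequence,
                        "n_diffs": d,
                    }
                )
        else:
            status = STATUS_CONSENSUS if g.consensus else STATUS_AUTHENTIC
            for cid in groups[g.anchor]:
                rows.append(
                    {
                        "clone_id": cid,
                        "status": status,
                        "target_sequence": g.sequence,
                        "n_diffs": 0,
                    }
                )
    return surviving, pd.DataFrame(rows)


@dataclass
class GenotypeTable:
    """Unique genotypes after QC with per-root-system clone counts."""

    table: pd.DataFrame  # genotype_id, sequence, n_clones, n_root_systems
    counts: pd.DataFrame  # genotype x root-system clone counts
    members: dict[str, list[str]]  # genotype_id -> clone ids

    def sequences(self) -> list[str]:
        return list(self.table["sequence"])


@dataclass
class QCResult:
    """Per-clone statuses and the dereplicated genotype table."""

    clone_status: pd.DataFrame  # clone_id, status, target_genotype, n_diffs
    genotypes: GenotypeTable
    chimera_report: pd.DataFrame

    @property
    def n_chimeric(self) -> int:
        return int((self.clone_status["status"] == STATUS_CHIMERIC).sum())


def run_qc(
    records: Sequence[CloneRecord],
    reference_db: ReferenceDB,
    min_region_identity: float = 0.80,
    max_collapse_diffs: int = 2,
) -> QCResult:
    """Full QC pass: chimera screen, then per-root-system error collapse,
    then dataset-wide dereplication into the genotype table."""
    chim = screen_chimeras(records, reference_db, min_region_identity)
    chimeric_ids = set(chim.loc[chim["is_chimera"], "clone_id"])

    by_rs: dict[str, list[CloneRecord]] = {}
    for r in records:
        if r.id not in chimeric_ids:
            by_rs.setdefault(r.root_system, []).append(r)

    # dataset-wide genotypes: pool identical post-collapse sequences
    seq_counts: dict[str, dict[str, list[str]]] = {}  # seq -> rs -> clone ids
    status_rows = []
    for rs in sorted(by_rs):
        genos, statuses = collapse_pcr_errors(by_rs[rs], max_collapse_diffs)
        status_rows.append(statuses)
        for g in genos:
            seq_counts.setdefault(g.sequence, {}).setdefault(rs, []).extend(g.members)

    ordered = sorted(
        seq_counts.items(),
        key=lambda kv: (-sum(len(v) for v in kv[1].values()), kv[0]),
    )
    rs_labels = sorted({r.root_system for r in records})
    geno_rows, count_rows, members = [], [], {}
    for n, (seq, per_rs) in enumerate(ordered, start=1):
        gid = f"G{n:04d}"
        clone_ids = [cid for rs in sorted(per_rs) for cid in per_rs[rs]]
        geno_rows.append(
            {
                "genotype_id": gid,
                "sequence": seq,
                "n_clones": len(clone_ids),
                "n_root_systems": len(per_rs),
            }
        )
        count_rows.append({rs: len(per_rs.get(rs, [])) for rs in rs_labels})
        members[gid] = clone_ids
    geno_table = pd.DataFrame(
        geno_rows, columns=["genotype_id", "sequence", "n_clones", "n_root_systems"]
    )
    counts = pd.DataFrame(count_rows, columns=rs_labels, dtype=int)
    if len(geno_table):
        counts.index = geno_table["genotype_id"]

    seq_to_gid = {row["sequence"]: row["genotype_id"] for row in geno_rows}
    status = (
        pd.concat(status_rows, ignore_index=True)
        if status_rows
        else pd.DataFrame(columns=["clone_id", "status", "target_sequence", "n_diffs"])
    )
    status["target_genotype"] = status["target_sequence"].map(seq_to_gid)
    status.loc[status["status"] == "collapsed", "status"] = [
        f"collapsed_into:{g}"
        for g in status.loc[status["status"] == "collapsed", "target_genotype"]
    ]
    status = status.drop(columns=["target_sequence"])
    chim_rows = pd.DataFrame(
        {
            "clone_id": sorted(chimeric_ids),
            "status": STATUS_CHIMERIC,
            "n_diffs": 0,
            "target_genotype": "",
        }
    )
    clone_status = pd.concat([status, chim_rows], ignore_index=True)
    genotable = GenotypeTable(geno_table, counts, members)
    return QCResult(clone_status, genotable, chim)
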