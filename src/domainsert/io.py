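"""Readers and writers: domain-assignment TSV, event tables, Cα traces.

The domain table dialect follows ECOD domain lists: one row per domain
instance, with discontinuity encoded in the residue-range string (never
as duplicate rows).  The event-table schema is frozen so downstream
analyses can rely on column order; floats are written with 6 significant
digits and output is bit-stable for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .detect import Gap, InsertionEvent
from .errors import ConfigError, DomainsertError, ValidationError
from .model import (
    DomainInstance,
    ProteinArchitecture,
    format_range_string,
    parse_family_id,
    parse_range_string,
)

__all__ = [
    "DOMAIN_TABLE_COLUMNS",
    "EVENT_TABLE_COLUMNS",
    "ReadReport",
    "CaTrace",
    "read_domain_table",
    "write_domain_table",
    "write_event_table",
    "read_event_table",
    "read_ca_trace",
    "write_ca_trace",
    "write_profile_table",
    "write_partnership_table",
    "write_enrichment_table",
    "write_termini_table",
]

DOMAIN_TABLE_COLUMNS = {
    "protein_id": "protein_id",
    "domain_uid": "domain_uid",
    "f_id": "f_id",
    "range": "range",
    "architecture": "architecture",  # optional
    "source": "source",  # optional
}

EVENT_TABLE_COLUMNS = [
    "protein_id",
    "host_uid",
    "host_f_id",
    "insert_uid",
    "insert_f_id",
    "gap_start",
    "gap_end",
    "depth",
    "host_length",
    "insert_length",
    "relative_position",
    "cross_h_group",
    "host_architecture",
    "insert_architecture",
]


@dataclass
class ReadReport:
    """Parse statistics from one domain-table read."""

    n_rows: int = 0
    n_proteins: int = 0
    n_discontinuous: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (row/protein id, reason)


def read_domain_table(
    path,
    columns: dict[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[ProteinArchitecture], ReadReport]:
    """Read a domain-assignment TSV into validated protein architectures.

    ``columns`` maps the standard column names (keys of
    ``DOMAIN_TABLE_COLUMNS``) to the actual header names.  Rows that fail
    validation (malformed range, bad family ID) and proteins whose domains
    overlap are rejected and recorded in the report; with ``strict=True``
    the first failure raises instead.  Reading is order-insensitive:
    shuffled input rows produce identical architectures.
    """
    colmap = dict(DOMAIN_TABLE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for std in ("protein_id", "domain_uid", "f_id", "range"):
        if colmap[std] not in df.columns:
            raise ConfigError(
                f"mandatory column {colmap[std]!r} (for {std}) missing from {path}"
            )
    report = ReadReport(n_rows=len(df))
    has_arch = colmap["architecture"] in df.columns

    domains_by_protein: dict[str, list[DomainInstance]] = {}
    for idx, row in df.iterrows():
        rid = f"row {idx} ({row[colmap['protein_id']]}/{row[colmap['domain_uid']]})"
        try:
            for std in ("protein_id", "domain_uid", "f_id", "range"):
                if not str(row[colmap[std]]).strip():
                    raise ValidationError(f"empty mandatory field {std}")
            segments, chain = parse_range_string(
                row[colmap["range"]], with_chain=True
            )
            dom = DomainInstance(
                protein_id=row[colmap["protein_id"]],
                domain_uid=row[colmap["domain_uid"]],
                family=parse_family_id(row[colmap["f_id"]]),
                segments=tuple(segments),
                architecture_label=(row[colmap["architecture"]] or None)
                if has_arch
                else None,
                chain=chain,
            )
        except DomainsertError as exc:
            if strict:
                raise
            report.rejected.append((rid, str(exc)))
            continue
        domains_by_protein.setdefault(dom.protein_id, []).append(dom)

    proteins: list[ProteinArchitecture] = []
    for pid in sorted(domains_by_protein):
        try:
            arch = ProteinArchitecture(pid, domains_by_protein[pid])
        except DomainsertError as exc:
            if strict:
                raise
            report.rejected.append((pid, str(exc)))
            continue
        proteins.append(arch)
        report.n_discontinuous += sum(d.discontinuous for d in arch.domains)
    report.n_proteins = len(proteins)
    return proteins, report


def write_domain_table(proteins: list[ProteinArchitecture], path) -> None:
    """Write protein architectures back to the domain-table dialect."""
    rows = []
    for p in proteins:
        for d in p.domains:
            rows.append(
                {
                    "protein_id": p.protein_id,
                    "domain_uid": d.domain_uid,
                    "f_id": d.family.f_id,
                    "range": format_range_string(list(d.segments)),
                    "architecture": d.architecture_label or "",
                }
            )
    pd.DataFrame(rows, columns=list(DOMAIN_TABLE_COLUMNS)[:5]).to_csv(
        path, sep="\t", index=False
    )


def _fmt6(x: float) -> str:
    return f"{x:.6g}"


def write_event_table(events: list[InsertionEvent], path) -> None:
    """Write insertion events as TSV with the frozen column order."""
    rows = []
    for e in events:
        rows.append(
            {
                "protein_id": e.protein_id,
                "host_uid": e.host_uid,
                "host_f_id": e.host_family.f_id,
                "insert_uid": e.insert_uid,
                "insert_f_id": e.insert_family.f_id,
                "gap_start": e.gap.start,
                "gap_end": e.gap.end,
                "depth": e.depth,
                "host_length": e.host_length,
                "insert_length": e.insert_length,
                "relative_position": _fmt6(e.relative_position),
                "cross_h_group": str(bool(e.cross_h_group)),
                "host_architecture": e.host_architecture or "",
                "insert_architecture": e.insert_architecture or "",
            }
        )
    pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_event_table(path) -> list[InsertionEvent]:
    """Read an event table written by :func:`write_event_table`.

    Gap indices are not serialised; they are reassigned per host in
    gap-start order, which reproduces the original indices for events
    produced by detection.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    events: list[InsertionEvent] = []
    # recompute gap_index: order of distinct gap starts per (protein, host)
    gap_orders: dict[tuple[str, str], list[int]] = {}
    for _, row in df.iterrows():
        key = (row["protein_id"], row["host_uid"])
        gap_orders.setdefault(key, []).append(int(row["gap_start"]))
    gap_index = {
        key: {s: i for i, s in enumerate(sorted(set(starts)))}
        for key, starts in gap_orders.items()
    }
    for _, row in df.iterrows():
        key = (row["protein_id"], row["host_uid"])
        gs = int(row["gap_start"])
        events.append(
            InsertionEvent(
                protein_id=row["protein_id"],
                host_uid=row["host_uid"],
                insert_uid=row["insert_uid"],
                host_family=parse_family_id(row["host_f_id"]),
                insert_family=parse_family_id(row["insert_f_id"]),
                gap=Gap(row["host_uid"], gap_index[key][gs], gs, int(row["gap_end"])),
                depth=int(row["depth"]),
                host_length=int(row["host_length"]),
                insert_length=int(row["insert_length"]),
                relative_position=float(row["relative_position"]),
                cross_h_group=row["cross_h_group"] == "True",
                host_architecture=row["host_architecture"] or None,
                insert_architecture=row["insert_architecture"] or None,
            )
        )
    return events


@dataclass
class CaTrace:
    """Ordered Cα coordinates of one chain, indices strictly increasing."""

    protein_id: str
    residues: np.ndarray  # (n,) residue indices
    coords: np.ndarray  # (n, 3) Cartesian coordinates, Angstrom

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.residues.ndim != 1 or self.coords.shape != (self.residues.size, 3):
            raise ValidationError("residues/coords shape mismatch")
        if self.residues.size == 0:
            raise ValidationError(f"trace {self.protein_id} has no Cα atoms")
        if np.any(np.diff(self.residues) <= 0):
            raise ValidationError(
                f"trace {self.protein_id}: residue indices not strictly increasing"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"trace {self.protein_id}: non-finite coordinates")

    def __len__(self) -> int:
        return self.residues.size

    def coord(self, residue: int) -> np.ndarray:
        """Cα position of one residue; KeyError if absent."""
        hit = np.nonzero(self.residues == residue)[0]
        if hit.size == 0:
            raise KeyError(f"no Cα for residue {residue} in {self.protein_id}")
        return self.coords[hit[0]]


def read_ca_trace(path, format: str = "auto", chain: str | None = None) -> CaTrace:
    """Read one chain's Cα trace from a PDB or mmCIF file (via gemmi).

    Altloc duplicates resolve to the highest occupancy, first-seen on
    ties.  ``format`` may be "pdb", "mmcif" or "auto" (by extension).
    """
    path = Path(path)
    if format == "pdb":
        st = gemmi.read_pdb(str(path))
    elif format == "mmcif":
        st = gemmi.cif.read(str(path))
        st = gemmi.make_structure_from_block(st.sole_block())
    elif format == "auto":
        st = gemmi.read_structure(str(path))
    else:
        raise ConfigError(f"unknown coordinate format {format!r}")
    if len(st) == 0:
        raise ValidationError(f"{path}: no models")
    model = st[0]
    if chain is None:
        ch = model[0] if len(model) else None
    else:
        ch = model.find_chain(chain)
    if ch is None:
        raise ValidationError(f"{path}: chain {chain!r} not found")
    residues = []
    coords = []
    for res in ch:
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is not None:
            residues.append(res.seqid.num)
            coords.append([best.pos.x, best.pos.y, best.pos.z])
    if not residues:
        raise ValidationError(f"{path}: zero Cα atoms in chain {ch.name!r}")
    return CaTrace(path.stem, np.array(residues), np.array(coords))


def write_ca_trace(trace: CaTrace, path, chain: str = "A") -> None:
    """Write a Cα-only trace as a minimal single-chain PDB file."""
    st = gemmi.Structure()
    st.name = trace.protein_id
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i, (resi, xyz) in enumerate(zip(trace.residues, trace.coords)):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(int(resi), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.occ = 1.0
        atom.b_iso = 0.0
        atom.serial = i + 1
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_minimal_pdb(str(path))


def _write_df(rows: list[dict], columns: list[str], path) -> None:
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_profile_table(profiles, path) -> None:
    _write_df(
        [
            {
                "f_id": p.family.f_id,
                "h_group": p.family.h_group,
                "x_group": p.family.x_group,
                "t_group_only": str(p.family.t_group_only),
                "host_events": p.host_events,
                "insert_events": p.insert_events,
                "total_events": p.total,
                "role": p.role,
                "mean_length_as_host": ""
                if p.mean_length_as_host is None
                else _fmt6(p.mean_length_as_host),
                "mean_length_as_insert": ""
                if p.mean_length_as_insert is None
                else _fmt6(p.mean_length_as_insert),
            }
            for p in profiles
        ],
        [
            "f_id",
            "h_group",
            "x_group",
            "t_group_only",
            "host_events",
            "insert_events",
            "total_events",
            "role",
            "mean_length_as_host",
            "mean_length_as_insert",
        ],
        path,
    )


def write_partnership_table(records, path) -> None:
    _write_df(
        [
            {
                "host_f_id": r.host_family.f_id,
                "insert_f_id": r.insert_family.f_id,
                "host_h_group": r.host_h_group,
                "insert_h_group": r.insert_h_group,
                "count": r.count,
                "cross_h_group": str(r.cross_h_group),
            }
            for r in records
        ],
        ["host_f_id", "insert_f_id", "host_h_group", "insert_h_group", "count", "cross_h_group"],
        path,
    )


def write_enrichment_table(results, path) -> None:
    _write_df(
        [
            {
                "group_id": r.group_id,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "log2_or": _fmt6(r.log2_or),
                "fisher_p": _fmt6(r.fisher_p),
                "fdr_q": _fmt6(r.fdr_q),
                "classification": r.classification,
                "significant": str(r.significant),
            }
            for r in results
        ],
        ["group_id", "a", "b", "c", "d", "log2_or", "fisher_p", "fdr_q", "classification", "significant"],
        path,
    )


def write_termini_table(comparisons, path) -> None:
    _write_df(
        [
            {
                "comparison": c.comparison,
                "size_bin": c.size_bin,
                "n_x": c.n_x,
                "n_y": c.n_y,
                "median_x": _fmt6(c.median_x),
                "median_y": _fmt6(c.median_y),
                "U": _fmt6(c.u),
                "rank_biserial_r": _fmt6(c.rank_biserial_r),
                "p_value": _fmt6(c.p_value),
                "underpowered": str(c.underpowered),
            }
            for c in comparisons
        ],
        ["comparison", "size_bin", "n_x", "n_y", "median_x", "median_y", "U", "rank_biserial_r", "p_value", "underpowered"],
        path,
    )
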