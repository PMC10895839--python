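"""Reaction data model, file I/O, and the curation pipeline.

A reaction is three role-tagged molecule lists (reactants, agents, products)
with an optional yield percentage. Curation proceeds as: canonicalize →
deduplicate → attach one conformer per molecule (dropping reactions where
embedding fails) → filter to valid yields (optionally subsampling low-yield
records) → split. Counts never increase along the pipeline and every drop is
recorded with a reason.

File formats: reaction-SMILES line files, CSV yield tables, SDF conformer
sidecars, CSV split manifests, and JSON curation reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule", "Reaction", "ReactionDataset", "CurationReport",
    "ReactionParseError", "ValidityError", "SplitError", "ConfigError", "DatasetIOError",
    "canonical_smiles", "parse_reaction_smiles", "canonicalize_reaction",
    "deduplicate_dataset", "attach_conformers", "filter_by_yield",
    "stratified_split", "split_by_component",
    "etkdg_embedder", "load_dataset", "write_dataset",
    "read_split_manifest", "write_split_manifest",
]

ROLES = ("reactants", "agents", "products")


class ReactionParseError(ValueError):
    pass


class ValidityError(ValueError):
    pass


class SplitError(ValueError):
    pass


class ConfigError(ValueError):
    pass


class DatasetIOError(ValueError):
    pass


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidityError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A molecule: canonical SMILES, ordered heavy-atom symbols, optional coords (Å)."""

    smiles: str
    atoms: tuple[str, ...] = ()
    coords: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=np.float64)
            if coords.shape != (len(self.atoms), 3):
                raise ValidityError(
                    f"molecule {self.smiles!r}: coords shape {coords.shape} does not "
                    f"match atom count {len(self.atoms)}"
                )
            if not np.all(np.isfinite(coords)):
                raise ValidityError(f"molecule {self.smiles!r}: non-finite coordinates")
            object.__setattr__(self, "coords", coords)

    @classmethod
    def from_smiles(cls, smiles: str, coords: Optional[np.ndarray] = None) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValidityError(f"invalid SMILES: {smiles!r}")
        canonical = Chem.MolToSmiles(mol)
        # reparse so atom order matches the canonical string
        mol = Chem.MolFromSmiles(canonical)
        atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
        return cls(canonical, atoms, coords)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        if self.smiles != other.smiles or self.atoms != other.atoms:
            return False
        if (self.coords is None) != (other.coords is None):
            return False
        return self.coords is None or np.array_equal(self.coords, other.coords)

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class Reaction:
    """Role-tagged molecule lists with an optional yield percentage.

    Yield validity ((0, 100]) is a *curation* rule, enforced by
    filter_by_yield, so raw records with out-of-range yields are
    representable.
    """

    reactants: tuple[Molecule, ...]
    agents: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    yield_pct: Optional[float] = None
    record_id: str = ""

    def __post_init__(self):
        if not self.reactants or not self.products:
            raise ValidityError(
                f"record {self.record_id!r}: reactants and products must be nonempty"
            )
        if self.n_molecules < 2:
            raise ValidityError(f"record {self.record_id!r}: a reaction needs >= 2 molecules")

    @property
    def n_molecules(self) -> int:
        return len(self.reactants) + len(self.agents) + len(self.products)

    def molecules(self) -> list[Molecule]:
        return list(self.reactants) + list(self.agents) + list(self.products)

    def canonical_molecule_order(self) -> list[Molecule]:
        """Reactants, agents, products; lexicographic by SMILES within role.

        Both the sequence view and the conformer view consume molecules in
        this order, so the two views always describe the same sequence.
        """
        out: list[Molecule] = []
        for role in (self.reactants, self.agents, self.products):
            out.extend(sorted(role, key=lambda m: m.smiles))
        return out

    def canonical_key(self) -> str:
        """Deduplication key: role-sorted canonical SMILES, yield excluded."""
        parts = []
        for role in (self.reactants, self.agents, self.products):
            parts.append(".".join(sorted(m.smiles for m in role)))
        return ">".join(parts)

    def reaction_smiles(self) -> str:
        parts = []
        for role in (self.reactants, self.agents, self.products):
            parts.append(".".join(m.smiles for m in role))
        return ">".join(parts)

    def has_conformers(self) -> bool:
        return all(m.coords is not None for m in self.molecules())

    def has_valid_yield(self) -> bool:
        y = self.yield_pct
        return y is not None and np.isfinite(y) and 0.0 < y <= 100.0


@dataclass
class ReactionDataset:
    """A list of reactions with optional split labels and provenance text."""

    records: list[Reaction] = field(default_factory=list)
    split_labels: Optional[dict[str, str]] = None
    provenance: str = ""

    def __post_init__(self):
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidityError("record_ids must be unique")
        if self.split_labels is not None:
            if set(self.split_labels) != set(ids):
                raise ValidityError("split labels must cover every record exactly once")
            bad = set(self.split_labels.values()) - {"train", "valid", "test"}
            if bad:
                raise ValidityError(f"unknown split labels: {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionDataset):
            return NotImplemented
        return (
            self.records == other.records
            and self.split_labels == other.split_labels
        )

    def subset(self, split: str) -> "ReactionDataset":
        if self.split_labels is None:
            raise SplitError("dataset has no split labels")
        recs = [r for r in self.records if self.split_labels[r.record_id] == split]
        return ReactionDataset(recs, None, provenance=f"{self.provenance} [{split}]")


@dataclass
class CurationReport:
    """Per-stage record counts plus the reason each dropped record fell out."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    dropped: list[dict[str, str]] = field(default_factory=list)

    def add_stage(self, name: str, count: int) -> None:
        # monotonicity is a pipeline invariant; catching it here makes a
        # violation loud instead of silently wrong
        if self.stage_counts:
            last = list(self.stage_counts.values())[-1]
            if count > last:
                raise ValidityError(
                    f"curation stage {name!r} increased the record count ({last} -> {count})"
                )
        self.stage_counts[name] = count

    def drop(self, record_id: str, stage: str, reason: str) -> None:
        self.dropped.append({"record_id": record_id, "stage": stage, "reason": reason})

    def merged_with(self, other: "CurationReport") -> "CurationReport":
        merged = CurationReport(dict(self.stage_counts), list(self.dropped))
        merged.stage_counts.update(other.stage_counts)
        merged.dropped.extend(other.dropped)
        return merged

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"stage_counts": self.stage_counts, "dropped": self.dropped}, indent=2)
        )


# ---------------------------------------------------------------------------
# parsing and canonicalization
# ---------------------------------------------------------------------------


def parse_reaction_smiles(text: str, yield_pct: Optional[float] = None,
                          record_id: str = "") -> Reaction:
    """Parse a "reactants>agents>products" string into a Reaction.

    Each molecule is canonicalized; the agents field may be empty.
    """
    parts = text.strip().split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"reaction SMILES must contain exactly two '>' separators, got {text!r}"
        )
    roles: list[tuple[Molecule, ...]] = []
    for part in parts:
        mols = []
        for frag in filter(None, part.split(".")):
            try:
                mols.append(Molecule.from_smiles(frag))
            except ValidityError as exc:
                raise ReactionParseError(f"unparseable fragment {frag!r} in {text!r}") from exc
        roles.append(tuple(mols))
    reactants, agents, products = roles
    if not reactants or not products:
        raise ReactionParseError(f"reactant and product fields must be nonempty in {text!r}")
    return Reaction(reactants, agents, products, yield_pct=yield_pct, record_id=record_id)


def canonicalize_reaction(r: Reaction) -> Reaction:
    """Canonicalize every molecule and sort each role lexicographically."""
    roles = []
    for role in (r.reactants, r.agents, r.products):
        mols = [
            Molecule.from_smiles(m.smiles, m.coords) if m.coords is not None
            else Molecule.from_smiles(m.smiles)
            for m in role
        ]
        roles.append(tuple(sorted(mols, key=lambda m: m.smiles)))
    return replace(r, reactants=roles[0], agents=roles[1], products=roles[2])


# ---------------------------------------------------------------------------
# curation pipeline
# ---------------------------------------------------------------------------


def deduplicate_dataset(d: ReactionDataset) -> tuple[ReactionDataset, CurationReport]:
    """Collapse records with identical canonical reaction keys.

    Among duplicates a record carrying a yield wins over one without;
    otherwise the first occurrence wins.
    """
    report = CurationReport()
    report.add_stage("input", len(d))
    kept: dict[str, Reaction] = {}
    for rec in d.records:
        key = rec.canonical_key()
        prev = kept.get(key)
        if prev is None:
            kept[key] = rec
        elif prev.yield_pct is None and rec.yield_pct is not None:
            report.drop(prev.record_id, "dedup", f"duplicate of {rec.record_id} (no yield)")
            kept[key] = rec
        else:
            report.drop(rec.record_id, "dedup", f"duplicate of {prev.record_id}")
    out = ReactionDataset(list(kept.values()), None, d.provenance)
    report.add_stage("after_dedup", len(out))
    return out, report


def _stable_seed(*parts) -> int:
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def etkdg_embedder(smiles: str, seed: int) -> Optional[np.ndarray]:
    """Generate one conformer with the ETKDG distance-geometry algorithm.

    Hydrogens are added for embedding and stripped afterwards; returns heavy-
    atom coordinates in the canonical-SMILES atom order, or None on failure.
    """
    mol = Chem.MolFromSmiles(canonical_smiles(smiles))
    if mol is None:
        return None
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        return None
    molh = Chem.RemoveHs(molh)
    conf = molh.GetConformer()
    return np.array(conf.GetPositions(), dtype=np.float64)


def attach_conformers(
    d: ReactionDataset,
    embedder: Callable[[str, int], Optional[np.ndarray]] = etkdg_embedder,
    seed: int = 0,
) -> tuple[ReactionDataset, CurationReport]:
    """Attach exactly one conformer per molecule; drop reactions where any
    molecule fails to embed.

    Coordinates are rounded to 4 decimal places (the SDF precision) so the
    on-disk representation round-trips exactly. The per-molecule embedding
    seed is derived from (seed, canonical SMILES), making results independent
    of record order; identical molecules share identical conformers.
    """
    report = CurationReport()
    report.add_stage("input", len(d))
    cache: dict[str, Optional[np.ndarray]] = {}
    kept: list[Reaction] = []
    for rec in d.records:
        new_roles: list[tuple[Molecule, ...]] = []
        failed: Optional[str] = None
        for role in (rec.reactants, rec.agents, rec.products):
            mols = []
            for m in role:
                if m.smiles not in cache:
                    cache[m.smiles] = embedder(m.smiles, _stable_seed(seed, m.smiles))
                coords = cache[m.smiles]
                if coords is None:
                    failed = m.smiles
                    break
                mols.append(Molecule(m.smiles, m.atoms, np.round(coords, 4)))
            if failed:
                break
            new_roles.append(tuple(mols))
        if failed:
            report.drop(rec.record_id, "conformers", f"embedding failed for {failed!r}")
            continue
        kept.append(replace(rec, reactants=new_roles[0], agents=new_roles[1],
                            products=new_roles[2]))
    out = ReactionDataset(kept, None, d.provenance)
    report.add_stage("after_conformers", len(out))
    return out, report


def filter_by_yield(
    d: ReactionDataset,
    low_cut: float = 50.0,
    low_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[ReactionDataset, CurationReport]:
    """Keep records with known, valid yields (numeric, in (0, 100]).

    Among the survivors with yield < low_cut, a seeded random fraction
    ``low_fraction`` is retained (the low-yield subsampling used when
    augmenting a biased corpus); low_fraction=1 keeps all of them.
    """
    if not 0.0 < low_cut <= 100.0:
        raise ConfigError(f"low_cut must be in (0, 100], got {low_cut}")
    if not 0.0 <= low_fraction <= 1.0:
        raise ConfigError(f"low_fraction must be in [0, 1], got {low_fraction}")
    report = CurationReport()
    report.add_stage("input", len(d))
    valid: list[Reaction] = []
    for rec in d.records:
        if rec.has_valid_yield():
            valid.append(rec)
        else:
            report.drop(rec.record_id, "yield_filter", f"invalid yield {rec.yield_pct!r}")
    if low_fraction < 1.0:
        low = [r for r in valid if r.yield_pct < low_cut]
        rng = np.random.default_rng(seed)
        n_keep = int(round(len(low) * low_fraction))
        chosen = rng.choice(len(low), size=n_keep, replace=False) if low else []
        keep_ids = {low[i].record_id for i in chosen}
        out_records = []
        for rec in valid:
            if rec.yield_pct < low_cut and rec.record_id not in keep_ids:
                report.drop(rec.record_id, "low_yield_sampling", "subsampled out")
            else:
                out_records.append(rec)
        valid = out_records
    out = ReactionDataset(valid, None, d.provenance)
    report.add_stage("after_yield_filter", len(out))
    return out, report


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def stratified_split(
    d: ReactionDataset,
    ratio: tuple[int, int, int] = (18, 1, 1),
    n_bins: int = 10,
    seed: int = 0,
) -> ReactionDataset:
    """Stratified train/valid/test split by yield.

    Records are binned into ``n_bins`` equal-width yield bins; within each bin
    the split proportions follow the global ratio to within one record, and
    the global sizes hit the largest-remainder targets exactly.
    """
    parts = np.asarray(ratio, dtype=float)
    if parts.sum() <= 0 or np.any(parts < 0):
        raise ConfigError(f"invalid split ratio {ratio}")
    n = len(d)
    if n < int(sum(1 for p in ratio if p > 0)):
        raise SplitError(f"too few records ({n}) for ratio {ratio}")
    fracs = parts / parts.sum()
    names = ("train", "valid", "test")

    # global targets by largest remainder
    raw = fracs * n
    target = np.floor(raw).astype(int)
    for k in np.argsort(-(raw - target)):
        if target.sum() == n:
            break
        target[k] += 1
    while target.sum() < n:  # pragma: no cover - safety
        target[np.argmax(raw - target)] += 1

    yields = np.array([r.yield_pct if r.yield_pct is not None else 0.0 for r in d.records])
    lo, hi = 0.0, 100.0
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, yields, side="right") - 1, 0, n_bins - 1)

    rng = np.random.default_rng(seed)
    labels: dict[str, str] = {}
    # per-bin floor allocation, then distribute global remainders to the bins
    # with the largest fractional quota, respecting bin capacity
    bins = [np.flatnonzero(bin_idx == b) for b in range(n_bins)]
    order = [rng.permutation(b) for b in bins]
    alloc = np.zeros((n_bins, 3), dtype=int)
    for b, members in enumerate(bins):
        alloc[b] = np.floor(fracs * len(members)).astype(int)
    for k in range(3):
        need = target[k] - alloc[:, k].sum()
        remainders = fracs[k] * np.array([len(b) for b in bins]) - alloc[:, k]
        for b in np.argsort(-remainders):
            if need <= 0:
                break
            if alloc[b].sum() < len(bins[b]):
                alloc[b, k] += 1
                need -= 1
        # if bins saturated, place leftovers anywhere with capacity
        b = 0
        while need > 0 and b < n_bins:
            while need > 0 and alloc[b].sum() < len(bins[b]):
                alloc[b, k] += 1
                need -= 1
            b += 1
    for b in range(n_bins):
        members = order[b]
        pos = 0
        for k, name in enumerate(names):
            for i in members[pos : pos + alloc[b, k]]:
                labels[d.records[i].record_id] = name
            pos += alloc[b, k]
        # any slack (rounding) goes to train
        for i in members[pos:]:
            labels[d.records[i].record_id] = "train"
    return ReactionDataset(list(d.records), labels, d.provenance)


def split_by_component(
    d: ReactionDataset,
    held_out: Iterable[str],
    role: str = "any",
) -> ReactionDataset:
    """Out-of-sample split: reactions containing a held-out component (in the
    given role, or anywhere for "any") go to test; all others to train.

    Guarantees zero leakage by construction; raises if a held-out SMILES never
    occurs in the dataset.
    """
    if role not in ROLES + ("any",):
        raise ConfigError(f"unknown role {role!r}")
    held = {canonical_smiles(s) for s in held_out}
    if not held:
        raise ConfigError("held_out set must be nonempty")
    seen: set[str] = set()
    labels: dict[str, str] = {}
    for rec in d.records:
        mols = rec.molecules() if role == "any" else list(getattr(rec, role))
        smls = {m.smiles for m in mols}
        hit = smls & held
        seen |= hit
        labels[rec.record_id] = "test" if hit else "train"
    missing = held - seen
    if missing:
        raise SplitError(f"held-out components not present in dataset: {sorted(missing)}")
    return ReactionDataset(list(d.records), labels, d.provenance)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_split_manifest(d: ReactionDataset, path: str | Path) -> None:
    if d.split_labels is None:
        raise DatasetIOError("dataset has no split labels to write")
    pd.DataFrame(
        [(r.record_id, d.split_labels[r.record_id]) for r in d.records],
        columns=["record_id", "split"],
    ).to_csv(path, index=False)


def read_split_manifest(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["record_id", "split"]:
        raise DatasetIOError(f"bad split manifest columns in {path}: {list(df.columns)}")
    return dict(zip(df["record_id"], df["split"]))


def _write_sdf(d: ReactionDataset, path: Path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetProps(["record_id", "mol_index", "role"])
    try:
        for rec in d.records:
            idx = 0
            for role in ROLES:
                for m in getattr(rec, role):
                    if m.coords is None:
                        idx += 1
                        continue
                    mol = Chem.MolFromSmiles(m.smiles)
                    conf = Chem.Conformer(mol.GetNumAtoms())
                    for a in range(mol.GetNumAtoms()):
                        conf.SetAtomPosition(a, m.coords[a].tolist())
                    mol.AddConformer(conf)
                    mol.SetProp("record_id", rec.record_id)
                    mol.SetProp("mol_index", str(idx))
                    mol.SetProp("role", role)
                    writer.write(mol)
                    idx += 1
    finally:
        writer.close()


def _read_sdf(path: Path) -> dict[tuple[str, int], np.ndarray]:
    coords: dict[tuple[str, int], np.ndarray] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for mol in supplier:
        if mol is None:
            raise DatasetIOError(f"unreadable molecule block in {path}")
        key = (mol.GetProp("record_id"), int(mol.GetProp("mol_index")))
        coords[key] = np.array(mol.GetConformer().GetPositions(), dtype=np.float64)
    return coords


def write_dataset(d: ReactionDataset, path: str | Path, format: str = "csv") -> None:
    """Write a dataset. Formats: "smiles" (one reaction per line), "csv"
    (record_id, reaction_smiles, yield_pct), each with optional SDF conformer
    sidecar (<path>.sdf) and split manifest (<path>.splits.csv).
    """
    path = Path(path)
    if format == "smiles":
        path.write_text("".join(r.reaction_smiles() + "\n" for r in d.records))
    elif format == "csv":
        pd.DataFrame(
            [(r.record_id, r.reaction_smiles(), r.yield_pct) for r in d.records],
            columns=["record_id", "reaction_smiles", "yield_pct"],
        ).to_csv(path, index=False)
    else:
        raise DatasetIOError(f"unknown format {format!r}")
    if any(rec.has_conformers() for rec in d.records):
        _write_sdf(d, path.with_suffix(path.suffix + ".sdf"))
    if d.split_labels is not None:
        write_split_manifest(d, path.with_suffix(path.suffix + ".splits.csv"))


def load_dataset(path: str | Path, format: str = "csv", supervised: bool = False) -> ReactionDataset:
    """Read a dataset written by write_dataset (conformers and splits are
    picked up from the sidecar files when present)."""
    path = Path(path)
    records: list[Reaction] = []
    if format == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                records.append(parse_reaction_smiles(line, record_id=f"line-{lineno}"))
            except ReactionParseError as exc:
                raise DatasetIOError(f"{path}:{lineno}: {exc}") from exc
    elif format == "csv":
        df = pd.read_csv(path)
        required = {"record_id", "reaction_smiles"}
        if not required <= set(df.columns):
            raise DatasetIOError(f"{path}: missing columns {required - set(df.columns)}")
        if supervised and "yield_pct" not in df.columns:
            raise DatasetIOError(f"{path}: yield_pct column required in supervised mode")
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            y = getattr(row, "yield_pct", None)
            y = None if y is None or pd.isna(y) else float(y)
            try:
                records.append(
                    parse_reaction_smiles(row.reaction_smiles, yield_pct=y,
                                          record_id=str(row.record_id))
                )
            except ReactionParseError as exc:
                raise DatasetIOError(f"{path}:{lineno}: {exc}") from exc
    else:
        raise DatasetIOError(f"unknown format {format!r}")

    sdf = path.with_suffix(path.suffix + ".sdf")
    if sdf.exists():
        coords = _read_sdf(sdf)
        merged = []
        for rec in records:
            roles: list[tuple[Molecule, ...]] = []
            idx = 0
            for role in ROLES:
                mols = []
                for m in getattr(rec, role):
                    c = coords.get((rec.record_id, idx))
                    if c is not None and c.shape[0] != len(m.atoms):
                        raise DatasetIOError(
                            f"{sdf}: record {rec.record_id} molecule {idx}: conformer "
                            f"has {c.shape[0]} atoms, molecule has {len(m.atoms)}"
                        )
                    mols.append(Molecule(m.smiles, m.atoms, c))
                    idx += 1
                roles.append(tuple(mols))
            merged.append(replace(rec, reactants=roles[0], agents=roles[1], products=roles[2]))
        records = merged

    split_labels = None
    manifest = path.with_suffix(path.suffix + ".splits.csv")
    if manifest.exists():
        split_labels = read_split_manifest(manifest)
    return ReactionDataset(records, split_labels)
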