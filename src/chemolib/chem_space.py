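"""Fingerprints, similarity coefficients and near-duplicate removal.

Fingerprints are abstract bit sets: downstream code (similarity scan,
dedup) never touches the chemistry toolkit, so tests and synthetic
benchmarks can inject constructed fingerprints directly.  When SMILES are
given, RDKit enumerates ECFP4/ECFP6 (Morgan radius 2/3, 2048 bits) and
MACCS keys (167 bits).

Similarity conventions follow common cheminformatics practice: Dice for
the ECFP kinds, Tanimoto for MACCS keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import CompoundRecord, ValidationError, logger

FP_KINDS: tuple[str, ...] = ("ECFP4", "ECFP6", "MACCS")

_DEFAULT_NBITS = {"ECFP4": 2048, "ECFP6": 2048, "MACCS": 167}


@dataclass(frozen=True)
class Fingerprint:
    """A binary molecular fingerprint as a set of set-bit indices."""

    kind: str
    bits: frozenset[int]
    nbits: int = 0  # 0 → kind default (2048 for ECFP kinds, 167 for MACCS)

    def __post_init__(self) -> None:
        if self.kind not in FP_KINDS:
            raise ValidationError(f"unknown fingerprint kind {self.kind!r}")
        if self.nbits == 0:
            object.__setattr__(self, "nbits", _DEFAULT_NBITS[self.kind])
        object.__setattr__(self, "bits", frozenset(int(b) for b in self.bits))
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValidationError(
                f"bit index out of range [0, {self.nbits}) for {self.kind}")


class FingerprintSet:
    """Per-compound fingerprints, possibly of several kinds.

    ``unfingerprintable`` lists compounds whose SMILES could not be parsed.
    """

    def __init__(self,
                 fps: Mapping[str, Mapping[str, Fingerprint]] | None = None,
                 unfingerprintable: Iterable[str] = ()):
        self._fps: dict[str, dict[str, Fingerprint]] = {
            cid: dict(kinds) for cid, kinds in (fps or {}).items()}
        self.unfingerprintable: set[str] = set(unfingerprintable)

    @property
    def compound_ids(self) -> list[str]:
        return list(self._fps)

    @property
    def kinds(self) -> list[str]:
        kinds: set[str] = set()
        for d in self._fps.values():
            kinds.update(d)
        return [k for k in FP_KINDS if k in kinds]

    def get(self, compound_id: str, kind: str) -> Fingerprint:
        return self._fps[compound_id][kind]

    def has(self, compound_id: str, kind: str) -> bool:
        return kind in self._fps.get(compound_id, {})

    def add(self, compound_id: str, fp: Fingerprint) -> None:
        self._fps.setdefault(compound_id, {})[fp.kind] = fp

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._fps

    def __len__(self) -> int:
        return len(self._fps)


def fingerprint_compounds(compounds: Sequence[CompoundRecord],
                          kinds: str | Sequence[str] = FP_KINDS,
                          ) -> FingerprintSet:
    """Enumerate fingerprints of the requested kind(s) from SMILES via RDKit.

    Compounds whose SMILES fail to parse are flagged un-fingerprintable
    (non-fatal); if every SMILES fails, an error is raised.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    if isinstance(kinds, str):
        kinds = (kinds,)
    gens = {}
    for kind in kinds:
        if kind == "ECFP4":
            gens[kind] = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        elif kind == "ECFP6":
            gens[kind] = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        elif kind != "MACCS":
            raise ValidationError(f"unknown fingerprint kind {kind!r}")

    out = FingerprintSet()
    for comp in compounds:
        mol = Chem.MolFromSmiles(comp.smiles) if comp.smiles else None
        if mol is None:
            out.unfingerprintable.add(comp.compound_id)
            logger.warning("compound %s: unparsable SMILES %r",
                           comp.compound_id, comp.smiles)
            continue
        for kind in kinds:
            if kind == "MACCS":
                bv = MACCSkeys.GenMACCSKeys(mol)
            else:
                bv = gens[kind].GetFingerprint(mol)
            out.add(comp.compound_id,
                    Fingerprint(kind, frozenset(bv.GetOnBits()), bv.GetNumBits()))
    if len(out) == 0:
        raise ValidationError("no compound produced a fingerprint "
                              "(all SMILES unparsable or missing)")
    return out


def _check_comparable(a: Fingerprint, b: Fingerprint) -> None:
    if a.kind != b.kind or a.nbits != b.nbits:
        raise ValidationError(
            f"cannot compare {a.kind}/{a.nbits} with {b.kind}/{b.nbits}")


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both sets are empty."""
    _check_comparable(a, b)
    denom = len(a.bits) + len(b.bits)
    if denom == 0:
        return 1.0
    return 2.0 * len(a.bits & b.bits) / denom


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |A∩B| / |A∪B|; 1.0 when both empty."""
    _check_comparable(a, b)
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Kind-appropriate similarity: Dice for ECFP4/6, Tanimoto for MACCS."""
    if a.kind == "MACCS":
        return tanimoto_similarity(a, b)
    return dice_similarity(a, b)


@dataclass
class DedupeReport:
    """Outcome of near-duplicate removal.

    ``removed`` holds, per removed compound, the cluster keeper and the
    strongest (kind, similarity) link between the two.
    """

    kept: list[str]
    removed: list[tuple[str, str, str, float]] = field(default_factory=list)

    @property
    def removed_ids(self) -> list[str]:
        return [r[0] for r in self.removed]


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def dedupe_near_duplicates(fps: FingerprintSet,
                           cutoff: float = 0.99,
                           order: Sequence[str] | None = None,
                           ) -> DedupeReport:
    """Remove structurally near-identical compounds.

    A pair is flagged when ANY available similarity (Dice-ECFP4, Dice-ECFP6,
    Tanimoto-MACCS) is >= ``cutoff``.  Flagged pairs are clustered by
    transitive closure; within each cluster the LAST compound in input order
    is kept and earlier members are removed (so of a duplicated pair listed
    first/second, the first is the one dropped).
    """
    if not (0 < cutoff <= 1):
        raise ValidationError("cutoff must be in (0, 1]")
    ids = list(order) if order is not None else fps.compound_ids
    if not ids:
        raise ValidationError("no compounds to dedupe")
    kinds = fps.kinds
    pos = {cid: i for i, cid in enumerate(ids)}

    uf = _UnionFind(ids)
    best_link: dict[tuple[str, str], tuple[str, float]] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            hit = None
            for kind in kinds:
                if not (fps.has(a, kind) and fps.has(b, kind)):
                    continue
                s = similarity(fps.get(a, kind), fps.get(b, kind))
                key = (a, b)
                if key not in best_link or s > best_link[key][1]:
                    best_link[key] = (kind, s)
                if s >= cutoff:
                    hit = kind
            if hit is not None:
                uf.union(a, b)

    clusters: dict[str, list[str]] = {}
    for cid in ids:
        clusters.setdefault(uf.find(cid), []).append(cid)

    kept, removed = [], []
    for members in clusters.values():
        members.sort(key=pos.__getitem__)
        keeper = members[-1]
        kept.append(keeper)
        for m in members[:-1]:
            key = (m, keeper) if pos[m] < pos[keeper] else (keeper, m)
            kind, s = best_link.get(key, ("ECFP4", float("nan")))
            removed.append((m, keeper, kind, s))
    kept.sort(key=pos.__getitem__)
    return DedupeReport(kept=kept, removed=removed)
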