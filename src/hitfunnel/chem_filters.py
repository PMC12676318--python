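"""Qualitative drug-likeness gate: Lipinski rule of five, PAINS and Brenk
structural alerts, and the combined pass rule used before docking.

A compound passes the qualitative gate only when it has zero Lipinski
violations AND no PAINS match AND no Brenk match.  HBA is counted as all
N+O (the rule's original convention) and HBD as N/O bearing at least one
hydrogen; logP is Wildman–Crippen ("WLogP") and TPSA is Ertl's fragment
scheme, both computed by RDKit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_model import CompoundRecord, MoleculeGraph

__all__ = [
    "DescriptorSet",
    "AlertCatalog",
    "LIPINSKI_THRESHOLDS",
    "compute_descriptors",
    "lipinski_violations",
    "alert_screen",
    "qualitative_pass",
    "deduplicate",
]

#: inclusive upper bounds; a descriptor exactly at the bound is compliant
LIPINSKI_THRESHOLDS = {"mw": 500.0, "hbd": 5, "hba": 10, "logp": 5.0}


@dataclass(frozen=True)
class DescriptorSet:
    """Rule-of-five inputs plus TPSA (Å²)."""

    mw: float  # g/mol
    hbd: int
    hba: int
    logp: float  # Wildman–Crippen
    tpsa: float  # Å²

    def __post_init__(self):
        if not self.mw > 0:
            raise ValueError("molecular weight must be positive")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("H-bond counts must be non-negative")


class AlertCatalog:
    """A named set of substructure alerts (PAINS or Brenk).

    Built either from the toolkit's bundled catalogs (which encode the
    original publications' SMARTS) via :meth:`pains` / :meth:`brenk`, or
    from explicit ``(pattern_id, SMARTS, description)`` entries.  Malformed
    patterns fail at load time, never at match time.
    """

    def __init__(self, name: str, entries: Sequence[tuple[str, str, str]]):
        from rdkit import Chem

        if not entries:
            raise ValueError("alert catalog must be non-empty")
        self.name = name
        self.entries = list(entries)
        self._queries = []
        for pid, smarts, desc in self.entries:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise ValueError(f"catalog {name}: pattern {pid!r} does not parse: {smarts!r}")
            self._queries.append((pid, q))
        self._rdkit_catalog = None

    def __len__(self) -> int:
        return len(self.entries) if self.entries else self._rdkit_catalog.GetNumEntries()

    @property
    def version(self) -> str:
        return f"{self.name} ({len(self)} patterns)"

    @classmethod
    def _from_builtin(cls, name: str, which) -> "AlertCatalog":
        from rdkit.Chem import FilterCatalog

        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(which)
        cat = FilterCatalog.FilterCatalog(params)
        obj = cls.__new__(cls)
        obj.name = name
        obj.entries = []
        obj._queries = []
        obj._rdkit_catalog = cat
        return obj

    @classmethod
    def pains(cls) -> "AlertCatalog":
        from rdkit.Chem import FilterCatalog

        return cls._from_builtin("PAINS", FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)

    @classmethod
    def brenk(cls) -> "AlertCatalog":
        from rdkit.Chem import FilterCatalog

        return cls._from_builtin("Brenk", FilterCatalog.FilterCatalogParams.FilterCatalogs.BRENK)

    def matches(self, rdmol) -> list[str]:
        if self._rdkit_catalog is not None:
            return sorted(e.GetDescription() for e in self._rdkit_catalog.GetMatches(rdmol))
        hit = []
        for pid, q in self._queries:
            if rdmol.HasSubstructMatch(q):
                hit.append(pid)
        return sorted(hit)


def _as_rdkit(mol):
    if isinstance(mol, MoleculeGraph):
        return mol.to_rdkit()
    return mol


def compute_descriptors(mol, tpsa_include_s_p: bool = True) -> DescriptorSet:
    """Compute MW, HBD, HBA (Lipinski N+O convention), WLogP and TPSA.

    Accepts a :class:`MoleculeGraph` or an RDKit Mol.  TPSA includes the
    sulfur/phosphorus fragment contributions by default — the convention
    the BOILED-Egg absorption model is parameterized on; pass
    ``tpsa_include_s_p=False`` for the original O/N-only scheme.
    """
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    rdmol = _as_rdkit(mol)
    # HBD counts donor *atoms* (any N/O bearing >=1 H), not N-H/O-H bonds
    hbd = sum(
        1 for a in rdmol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() >= 1
    )
    return DescriptorSet(
        mw=Descriptors.MolWt(rdmol),
        hbd=hbd,
        hba=rdMolDescriptors.CalcNumLipinskiHBA(rdmol),
        logp=Crippen.MolLogP(rdmol),
        tpsa=rdMolDescriptors.CalcTPSA(rdmol, includeSandP=tpsa_include_s_p),
    )


def lipinski_violations(desc: DescriptorSet) -> tuple[int, dict[str, bool]]:
    """Count rule-of-five violations; bounds are inclusive (≤ passes).

    Returns ``(count, flags)`` where ``flags[rule]`` is True when violated.
    """
    flags = {
        "mw": desc.mw > LIPINSKI_THRESHOLDS["mw"],
        "hbd": desc.hbd > LIPINSKI_THRESHOLDS["hbd"],
        "hba": desc.hba > LIPINSKI_THRESHOLDS["hba"],
        "logp": desc.logp > LIPINSKI_THRESHOLDS["logp"],
    }
    return sum(flags.values()), flags


def alert_screen(mol, catalog: AlertCatalog) -> list[str]:
    """Return ids of catalog patterns with ≥1 embedding in the molecule."""
    return catalog.matches(_as_rdkit(mol))


def qualitative_pass(
    mol,
    catalogs: Optional[Sequence[AlertCatalog]] = None,
    max_violations: int = 0,
) -> tuple[bool, list[str]]:
    """Combined gate: no Lipinski violations and no structural alerts.

    ``max_violations`` relaxes the Lipinski part (some pipelines allow 1);
    the default is strict.  Returns ``(passed, reasons)`` where reasons name
    each failure as ``"Lipinski:<rule>"``, ``"PAINS:<id>"`` or ``"Brenk:<id>"``.
    """
    if catalogs is None:
        catalogs = [AlertCatalog.pains(), AlertCatalog.brenk()]
    rdmol = _as_rdkit(mol)
    reasons: list[str] = []
    count, flags = lipinski_violations(compute_descriptors(rdmol))
    if count > max_violations:
        reasons.extend(f"Lipinski:{rule}" for rule, bad in flags.items() if bad)
    for cat in catalogs:
        reasons.extend(f"{cat.name}:{pid}" for pid in cat.matches(rdmol))
    return (not reasons, reasons)


def deduplicate(
    records: Sequence[CompoundRecord],
    by_structure: bool = False,
) -> tuple[list[CompoundRecord], int]:
    """Drop repeated hits, keeping the first occurrence.

    Default key is the compound id; ``by_structure=True`` collapses records
    whose SMILES canonicalize identically (ids may differ between vendor
    libraries).  Returns ``(unique_records, n_duplicates)``.
    """
    seen: set[str] = set()
    out: list[CompoundRecord] = []
    if by_structure:
        from rdkit import Chem

    for rec in records:
        if by_structure and rec.smiles:
            mol = Chem.MolFromSmiles(rec.smiles)
            key = "smi:" + (Chem.MolToSmiles(mol) if mol is not None else rec.smiles)
        else:
            key = "id:" + rec.id
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out, len(records) - len(out)
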