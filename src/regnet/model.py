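"""Domain model for qualitative regulatory interactions.

The model follows the declarative-regulation idiom used by curated
prokaryotic databases: a regulatory interaction is a single record (a
``Regulation``) naming a regulator entity, a regulated entity and a mode
(sign), rather than an explicit chain of binding reactions.  Regulation of a
promoter implicitly regulates every gene of the promoter's transcription
unit; regulation of a terminator (attenuation) regulates only the genes
downstream of the potential terminator; translational regulation targets a
transcription unit or a single gene.  Post-translational events (covalent
modification, sequestration) are represented as ordinary :class:`Reaction`
records, never as ``Regulation`` records.

All identifiers are case-sensitive opaque strings and must be globally
unique across entity kinds, so that a regulated-entity reference is
unambiguous.  Gene order within a transcription unit is authoritative for
attenuation semantics; genomic coordinates are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Gene",
    "TranscriptionUnit",
    "Promoter",
    "Terminator",
    "Product",
    "Compound",
    "Reaction",
    "Regulation",
    "RegulatoryModel",
    "ValidationReport",
    "ModelStats",
    "ModelError",
    "UnresolvedEntityError",
    "validate_model",
    "regulated_genes",
    "regulator_genes",
    "product_genes",
    "regulator_category",
    "model_stats",
    "TRANSCRIPTIONAL_CLASSES",
    "TRANSLATIONAL_CLASSES",
    "EXPRESSION_CLASSES",
    "REGULATION_CLASSES",
    "MODES",
]

# Regulation class vocabulary.  "regulation-of-protein-degradation" is
# reserved in the vocabulary but rejected by validation: degradation
# regulation is not supported by this model.
TF_BINDING = "transcription-factor-binding"
ALLOSTERIC_RNAP = "allosteric-regulation-of-rnap"
ATTENUATION = "transcriptional-attenuation"
TRANSLATION = "regulation-of-translation"
ENZYME_ACTIVITY = "regulation-of-enzyme-activity"
PROTEIN_DEGRADATION = "regulation-of-protein-degradation"

TRANSCRIPTIONAL_CLASSES = frozenset({TF_BINDING, ALLOSTERIC_RNAP, ATTENUATION})
TRANSLATIONAL_CLASSES = frozenset({TRANSLATION})
EXPRESSION_CLASSES = TRANSCRIPTIONAL_CLASSES | TRANSLATIONAL_CLASSES
REGULATION_CLASSES = EXPRESSION_CLASSES | {ENZYME_ACTIVITY}

MODES = ("+", "-", "dual", "unknown")
PRODUCT_KINDS = ("polypeptide", "rna", "complex", "modified-form")

TRANSLATION_SUB_CLASSES = ("protein-mediated", "rna-mediated", "compound-mediated")
TRANSLATION_MECHANISMS = ("ribosome-blocking", "mrna-degradation", "both")


class ModelError(Exception):
    """Raised for structural problems that prevent an operation entirely."""


class UnresolvedEntityError(ModelError):
    """An entity id referenced by an operation does not resolve."""

    def __init__(self, entity_id: str, context: str = ""):
        self.entity_id = entity_id
        msg = f"unresolved entity id {entity_id!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


@dataclass
class Gene:
    id: str
    name: str = ""
    product_id: Optional[str] = None


@dataclass
class TranscriptionUnit:
    """One or more genes transcribed together from a single promoter.

    ``gene_ids`` are ordered promoter-proximal first; this order carries the
    attenuation semantics (a terminator after the k-th gene spares the first
    k genes).
    """

    id: str
    gene_ids: list[str] = field(default_factory=list)
    promoter_id: Optional[str] = None
    terminator_ids: list[str] = field(default_factory=list)


@dataclass
class Promoter:
    id: str
    tu_id: str = ""
    sigma_factor_id: Optional[str] = None


@dataclass
class Terminator:
    """A potential terminator inside a TU.

    ``site_index`` = k means the terminator lies after the k-th gene of the
    owning TU (counting from 1); attenuation through this terminator
    regulates only the genes with index > k.
    """

    id: str
    tu_id: str = ""
    site_index: int = 0


@dataclass
class Product:
    id: str
    kind: str = "polypeptide"
    gene_ids: list[str] = field(default_factory=list)
    component_ids: list[str] = field(default_factory=list)
    unmodified_form_id: Optional[str] = None
    ligand_ids: list[str] = field(default_factory=list)


@dataclass
class Compound:
    id: str
    name: str = ""


@dataclass
class Reaction:
    id: str
    reactant_ids: list[str] = field(default_factory=list)
    product_ids: list[str] = field(default_factory=list)
    enzyme_ids: list[str] = field(default_factory=list)
    reversible: bool = False


@dataclass
class BindingSite:
    position: int = 0
    description: str = ""


@dataclass
class Regulation:
    """A single qualitative regulatory interaction.

    ``mode`` is "+" (activation), "-" (inhibition), "dual" (both, depending
    on context) or "unknown".  ``sub_class`` refines the class (e.g. the
    attenuation mechanism, or protein-/rna-/compound-mediated translation
    regulation); ``mechanism`` is a free refinement such as "allosteric" or
    "ribosome-blocking".  ``physiologically_relevant`` distinguishes in-vivo
    relevant enzyme modulation from purely in-vitro observations.
    """

    id: str
    reg_class: str = TF_BINDING
    regulator_id: str = ""
    regulated_entity_id: str = ""
    mode: str = "unknown"
    sub_class: Optional[str] = None
    mechanism: Optional[str] = None
    physiologically_relevant: Optional[bool] = None
    binding_site: Optional[BindingSite] = None


@dataclass
class RegulatoryModel:
    """Container of all entities, with derived lookup indices.

    Equality compares the entity tables only; indices are derived and are
    rebuilt by :meth:`reindex`.
    """

    genes: dict[str, Gene] = field(default_factory=dict)
    transcription_units: dict[str, TranscriptionUnit] = field(default_factory=dict)
    promoters: dict[str, Promoter] = field(default_factory=dict)
    terminators: dict[str, Terminator] = field(default_factory=dict)
    products: dict[str, Product] = field(default_factory=dict)
    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    regulations: dict[str, Regulation] = field(default_factory=dict)

    # derived indices (not part of equality)
    gene_to_tus: dict[str, list[str]] = field(default_factory=dict, compare=False, repr=False)
    regs_by_regulated: dict[str, list[str]] = field(default_factory=dict, compare=False, repr=False)
    regs_by_regulator: dict[str, list[str]] = field(default_factory=dict, compare=False, repr=False)
    compound_to_reactions: dict[str, list[str]] = field(default_factory=dict, compare=False, repr=False)

    def reindex(self) -> "RegulatoryModel":
        self.gene_to_tus = {}
        for tu in self.transcription_units.values():
            for g in tu.gene_ids:
                self.gene_to_tus.setdefault(g, []).append(tu.id)
        for tus in self.gene_to_tus.values():
            tus.sort()
        self.regs_by_regulated = {}
        self.regs_by_regulator = {}
        for reg in self.regulations.values():
            self.regs_by_regulated.setdefault(reg.regulated_entity_id, []).append(reg.id)
            self.regs_by_regulator.setdefault(reg.regulator_id, []).append(reg.id)
        for lst in self.regs_by_regulated.values():
            lst.sort()
        for lst in self.regs_by_regulator.values():
            lst.sort()
        self.compound_to_reactions = {}
        for rxn in self.reactions.values():
            for cid in set(rxn.reactant_ids) | set(rxn.product_ids):
                if cid in self.compounds:
                    self.compound_to_reactions.setdefault(cid, []).append(rxn.id)
        for lst in self.compound_to_reactions.values():
            lst.sort()
        return self

    # -- entity lookup helpers -------------------------------------------
    def entity_kind(self, entity_id: str) -> Optional[str]:
        for kind, table in (
            ("gene", self.genes),
            ("transcription_unit", self.transcription_units),
            ("promoter", self.promoters),
            ("terminator", self.terminators),
            ("product", self.products),
            ("compound", self.compounds),
            ("reaction", self.reactions),
            ("regulation", self.regulations),
        ):
            if entity_id in table:
                return kind
        return None

    def has_entity(self, entity_id: str) -> bool:
        return self.entity_kind(entity_id) is not None


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, entity_id: str, message: str) -> None:
        self.errors.append((entity_id, message))

    def summary(self) -> str:
        if self.ok:
            return "model valid: 0 errors"
        lines = [f"model invalid: {len(self.errors)} error(s)"]
        lines += [f"  {eid}: {msg}" for eid, msg in self.errors]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# validation


def _check_unique_ids(model: RegulatoryModel, report: ValidationReport) -> None:
    seen: dict[str, str] = {}
    for kind, table in (
        ("gene", model.genes),
        ("transcription_unit", model.transcription_units),
        ("promoter", model.promoters),
        ("terminator", model.terminators),
        ("product", model.products),
        ("compound", model.compounds),
        ("reaction", model.reactions),
        ("regulation", model.regulations),
    ):
        for eid in table:
            if eid in seen:
                report.add(eid, f"id used by both {seen[eid]} and {kind}")
            else:
                seen[eid] = kind


def _component_graph_acyclic(model: RegulatoryModel) -> list[str]:
    """Return product ids participating in a component/modified-form cycle."""
    state: dict[str, int] = {}  # 0 visiting, 1 done
    bad: set[str] = set()

    def visit(pid: str, stack: set[str]) -> None:
        if pid in state:
            if state[pid] == 0:
                bad.update(stack)
            return
        state[pid] = 0
        prod = model.products.get(pid)
        if prod is not None:
            refs = [c for c in prod.component_ids if c in model.products]
            if prod.unmodified_form_id:
                refs.append(prod.unmodified_form_id)
            for ref in refs:
                if ref in stack:
                    bad.add(ref)
                    bad.add(pid)
                else:
                    visit(ref, stack | {pid})
        state[pid] = 1

    for pid in model.products:
        if pid not in state:
            visit(pid, set())
    return sorted(bad)


_REG_CLASS_TARGET_KINDS = {
    TF_BINDING: {"promoter"},
    ALLOSTERIC_RNAP: {"promoter"},
    ATTENUATION: {"terminator"},
    TRANSLATION: {"transcription_unit", "gene"},
    ENZYME_ACTIVITY: {"reaction", "product"},
}


def validate_model(model: RegulatoryModel) -> ValidationReport:
    """Check every structural invariant; violations are data, not exceptions."""
    report = ValidationReport()
    _check_unique_ids(model, report)

    for gene in model.genes.values():
        if gene.product_id is not None and gene.product_id not in model.products:
            report.add(gene.id, f"product_id {gene.product_id!r} does not resolve to a product")

    for tu in model.transcription_units.values():
        if not tu.gene_ids:
            report.add(tu.id, "transcription unit has no genes")
        if len(set(tu.gene_ids)) != len(tu.gene_ids):
            report.add(tu.id, "duplicate gene ids in transcription unit")
        for g in tu.gene_ids:
            if g not in model.genes:
                report.add(tu.id, f"gene {g!r} does not resolve")
        if tu.promoter_id is not None:
            prom = model.promoters.get(tu.promoter_id)
            if prom is None:
                report.add(tu.id, f"promoter {tu.promoter_id!r} does not resolve")
            elif prom.tu_id != tu.id:
                report.add(tu.id, f"promoter {prom.id!r} does not point back to this TU")
        for t in tu.terminator_ids:
            term = model.terminators.get(t)
            if term is None:
                report.add(tu.id, f"terminator {t!r} does not resolve")
            elif term.tu_id != tu.id:
                report.add(tu.id, f"terminator {t!r} belongs to TU {term.tu_id!r}")

    for prom in model.promoters.values():
        tu = model.transcription_units.get(prom.tu_id)
        if tu is None:
            report.add(prom.id, f"tu_id {prom.tu_id!r} does not resolve")
        elif tu.promoter_id != prom.id:
            report.add(prom.id, f"owning TU {tu.id!r} does not reference this promoter")
        if prom.sigma_factor_id is not None and prom.sigma_factor_id not in model.products:
            report.add(prom.id, f"sigma factor {prom.sigma_factor_id!r} does not resolve to a product")

    for term in model.terminators.values():
        tu = model.transcription_units.get(term.tu_id)
        if tu is None:
            report.add(term.id, f"tu_id {term.tu_id!r} does not resolve")
        elif not (0 <= term.site_index < len(tu.gene_ids)):
            report.add(
                term.id,
                f"site_index {term.site_index} out of range for TU with {len(tu.gene_ids)} gene(s)",
            )

    for prod in model.products.values():
        if prod.kind not in PRODUCT_KINDS:
            report.add(prod.id, f"unknown product kind {prod.kind!r}")
            continue
        if prod.kind in ("polypeptide", "rna"):
            if not prod.gene_ids:
                report.add(prod.id, f"{prod.kind} has no encoding gene")
            if prod.component_ids:
                report.add(prod.id, f"{prod.kind} must not have components")
        elif prod.kind == "complex":
            if not prod.component_ids:
                report.add(prod.id, "complex has no components")
        elif prod.kind == "modified-form":
            if not prod.unmodified_form_id:
                report.add(prod.id, "modified form lacks unmodified_form_id")
            elif prod.unmodified_form_id not in model.products:
                report.add(prod.id, f"unmodified form {prod.unmodified_form_id!r} does not resolve")
        for g in prod.gene_ids:
            if g not in model.genes:
                report.add(prod.id, f"encoding gene {g!r} does not resolve")
        for c in prod.component_ids:
            if c not in model.products and c not in model.compounds:
                report.add(prod.id, f"component {c!r} is neither product nor compound")
        for lig in prod.ligand_ids:
            if lig not in model.compounds:
                report.add(prod.id, f"ligand {lig!r} does not resolve to a compound")

    for pid in _component_graph_acyclic(model):
        report.add(pid, "product participates in a component/modified-form cycle")

    for rxn in model.reactions.values():
        if not rxn.reactant_ids:
            report.add(rxn.id, "reaction has no reactants")
        if not rxn.product_ids:
            report.add(rxn.id, "reaction has no products")
        for eid in rxn.reactant_ids + rxn.product_ids:
            if eid not in model.compounds and eid not in model.products:
                report.add(rxn.id, f"participant {eid!r} does not resolve")
        for eid in rxn.enzyme_ids:
            if eid not in model.products:
                report.add(rxn.id, f"enzyme {eid!r} does not resolve to a product")

    for reg in model.regulations.values():
        if reg.reg_class == PROTEIN_DEGRADATION:
            report.add(reg.id, "regulation of protein degradation is not supported")
            continue
        if reg.reg_class not in REGULATION_CLASSES:
            report.add(reg.id, f"unknown regulation class {reg.reg_class!r}")
            continue
        if reg.mode not in MODES:
            report.add(reg.id, f"unknown mode {reg.mode!r}")
        if reg.regulator_id not in model.products and reg.regulator_id not in model.compounds:
            report.add(reg.id, f"regulator {reg.regulator_id!r} does not resolve to a product or compound")
        target_kind = model.entity_kind(reg.regulated_entity_id)
        if target_kind is None:
            report.add(reg.id, f"regulated entity {reg.regulated_entity_id!r} does not resolve")
        elif target_kind not in _REG_CLASS_TARGET_KINDS[reg.reg_class]:
            report.add(
                reg.id,
                f"regulated entity kind {target_kind!r} incompatible with class {reg.reg_class!r}",
            )

    return report


# ---------------------------------------------------------------------------
# expansion semantics


def regulated_genes(reg: Regulation, model: RegulatoryModel) -> list[str]:
    """Genes affected by a regulation, by the expansion rules of the ontology.

    Promoter target: every gene of the promoter's TU (in TU order).
    Terminator target (attenuation): only genes downstream of the potential
    terminator.  TU target: every TU gene.  Gene target: that gene.
    Reaction/enzyme targets do not expand to genes.
    """
    eid = reg.regulated_entity_id
    if eid in model.promoters:
        tu = model.transcription_units.get(model.promoters[eid].tu_id)
        if tu is None:
            raise UnresolvedEntityError(model.promoters[eid].tu_id, f"TU of promoter {eid}")
        return list(tu.gene_ids)
    if eid in model.terminators:
        term = model.terminators[eid]
        tu = model.transcription_units.get(term.tu_id)
        if tu is None:
            raise UnresolvedEntityError(term.tu_id, f"TU of terminator {eid}")
        return list(tu.gene_ids[term.site_index:])
    if eid in model.transcription_units:
        return list(model.transcription_units[eid].gene_ids)
    if eid in model.genes:
        return [eid]
    if eid in model.reactions or eid in model.products:
        return []
    raise UnresolvedEntityError(eid, f"regulated entity of {reg.id}")


def product_genes(entity_id: str, model: RegulatoryModel) -> list[str]:
    """Recursively resolve an entity to the genes encoding it (sorted, unique).

    Polypeptides and RNAs resolve to their encoding genes; modified forms to
    the genes of the unmodified form; complexes to the union over product
    components (compound components encode nothing); compounds to nothing.
    """
    out: set[str] = set()
    seen: set[str] = set()

    def walk(eid: str) -> None:
        if eid in seen:
            return
        seen.add(eid)
        if eid in model.genes:
            out.add(eid)
            return
        if eid in model.compounds:
            return
        prod = model.products.get(eid)
        if prod is None:
            raise UnresolvedEntityError(eid, "regulator resolution")
        if prod.kind in ("polypeptide", "rna"):
            out.update(prod.gene_ids)
        elif prod.kind == "modified-form":
            if prod.unmodified_form_id:
                walk(prod.unmodified_form_id)
        elif prod.kind == "complex":
            for c in prod.component_ids:
                walk(c)

    walk(entity_id)
    return sorted(out)


def regulator_genes(reg: Regulation, model: RegulatoryModel) -> list[str]:
    """Genes encoding the regulator entity of a regulation (sorted, unique)."""
    return product_genes(reg.regulator_id, model)


def regulator_category(entity_id: str, model: RegulatoryModel) -> str:
    """Classify a regulator entity as 'protein', 'rna' or 'small-molecule'.

    Compounds are small molecules.  An RNA product is RNA; a complex counts
    as protein if any component (recursively) is a polypeptide, as RNA if
    any is an RNA and none is a polypeptide, else as small molecule.
    Modified forms classify as their unmodified base.
    """
    if entity_id in model.compounds:
        return "small-molecule"
    prod = model.products.get(entity_id)
    if prod is None:
        raise UnresolvedEntityError(entity_id, "regulator category")
    if prod.kind == "polypeptide":
        return "protein"
    if prod.kind == "rna":
        return "rna"
    if prod.kind == "modified-form":
        if prod.unmodified_form_id:
            return regulator_category(prod.unmodified_form_id, model)
        return "protein"
    # complex: inspect components
    cats = set()
    for c in prod.component_ids:
        if c in model.compounds:
            cats.add("small-molecule")
        else:
            cats.add(regulator_category(c, model))
    if "protein" in cats:
        return "protein"
    if "rna" in cats:
        return "rna"
    return "small-molecule"


# ---------------------------------------------------------------------------
# model statistics


@dataclass
class ModelStats:
    """Regulation-content tallies, one field per reporting category.

    ``transcriptional_regulation`` counts all transcriptional-class records
    (transcription-factor binding + allosteric regulation of RNA polymerase
    + attenuation); translational sub-rows split by mediator.  Regulator
    tallies count distinct regulator entities of expression regulations,
    split by chemical category.  Enzyme-modulation tallies are reported both
    unfiltered and restricted to physiologically relevant records.
    """

    transcriptional_regulation: int = 0
    tf_binding: int = 0
    allosteric_rnap: int = 0
    attenuation: int = 0
    translational_regulation: int = 0
    translational_protein_mediated: int = 0
    translational_rna_mediated: int = 0
    translational_compound_mediated: int = 0
    enzyme_modulation: int = 0
    enzyme_modulation_physiological: int = 0
    genes_with_regulator: int = 0
    genes_with_regulator_fraction: float = 0.0
    regulators_total: int = 0
    regulators_protein: int = 0
    regulators_rna: int = 0
    regulators_small_molecule: int = 0
    enzymes_modulated: int = 0
    enzymes_modulated_physiological: int = 0
    enzyme_modulators: int = 0
    enzyme_modulators_physiological: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _modulated_enzymes(reg: Regulation, model: RegulatoryModel) -> set[str]:
    """Enzyme product ids touched by one enzyme-activity regulation."""
    eid = reg.regulated_entity_id
    if eid in model.products:
        return {eid}
    rxn = model.reactions.get(eid)
    if rxn is not None:
        return set(rxn.enzyme_ids)
    return set()


def model_stats(model: RegulatoryModel, physiological_only: bool = False) -> ModelStats:
    """Tally regulation content by category.

    Gene coverage is computed through :func:`regulated_genes` over all
    transcriptional and translational regulations.  With
    ``physiological_only`` the enzyme-modulation tallies count only records
    flagged physiologically relevant (the dedicated ``*_physiological``
    fields always do).
    """
    st = ModelStats()
    covered: set[str] = set()
    expr_regulators: dict[str, str] = {}
    enzymes_all: set[str] = set()
    enzymes_phys: set[str] = set()
    modulators_all: set[str] = set()
    modulators_phys: set[str] = set()

    for reg in model.regulations.values():
        cls = reg.reg_class
        if cls in TRANSCRIPTIONAL_CLASSES:
            st.transcriptional_regulation += 1
            if cls == TF_BINDING:
                st.tf_binding += 1
            elif cls == ALLOSTERIC_RNAP:
                st.allosteric_rnap += 1
            else:
                st.attenuation += 1
        elif cls in TRANSLATIONAL_CLASSES:
            st.translational_regulation += 1
            if reg.sub_class == "protein-mediated":
                st.translational_protein_mediated += 1
            elif reg.sub_class == "rna-mediated":
                st.translational_rna_mediated += 1
            elif reg.sub_class == "compound-mediated":
                st.translational_compound_mediated += 1
        elif cls == ENZYME_ACTIVITY:
            phys = reg.physiologically_relevant is True
            if phys:
                st.enzyme_modulation_physiological += 1
                enzymes_phys |= _modulated_enzymes(reg, model)
                modulators_phys.add(reg.regulator_id)
            if not physiological_only or phys:
                st.enzyme_modulation += 1
                enzymes_all |= _modulated_enzymes(reg, model)
                modulators_all.add(reg.regulator_id)
        if cls in EXPRESSION_CLASSES:
            covered.update(regulated_genes(reg, model))
            if reg.regulator_id not in expr_regulators:
                expr_regulators[reg.regulator_id] = regulator_category(reg.regulator_id, model)

    st.genes_with_regulator = len(covered)
    if model.genes:
        st.genes_with_regulator_fraction = len(covered) / len(model.genes)
    st.regulators_total = len(expr_regulators)
    for cat in expr_regulators.values():
        if cat == "protein":
            st.regulators_protein += 1
        elif cat == "rna":
            st.regulators_rna += 1
        else:
            st.regulators_small_molecule += 1
    st.enzymes_modulated = len(enzymes_all)
    st.enzymes_modulated_physiological = len(enzymes_phys)
    st.enzyme_modulators = len(modulators_all)
    st.enzyme_modulators_physiological = len(modulators_phys)
    return st
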