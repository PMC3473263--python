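"""Seeded generator of synthetic regulatory models with a ground-truth ledger.

The generator emits a complete RegJSON-serializable model with the
structural features of curated prokaryotic regulatory databases: genes
partitioned into transcription units by a geometric operon-size
distribution, one promoter per TU with a sigma factor, transcription
factors with Poisson-sized regulons (some acting as ligand-bound complexes
or covalently modified forms), attenuation terminators inside multi-gene
operons, translational regulation by proteins, small RNAs and riboswitch
ligands, and a metabolic layer of compounds, reactions and substrate-level
enzyme modulation, including deliberately wired hub metabolites.

Every random draw comes from named substreams of a single master seed, so
regeneration is bit-for-bit reproducible and adding a feature never
perturbs earlier streams.  Alongside the model the generator records a
:class:`GroundTruthLedger` — exact per-category counts and per-regulator
target lists written down *during* construction — so that analysis results
computed from the emitted model can be checked against construction-time
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ALLOSTERIC_RNAP,
    ATTENUATION,
    ENZYME_ACTIVITY,
    TF_BINDING,
    TRANSLATION,
    Compound,
    Gene,
    ModelStats,
    Product,
    Promoter,
    Reaction,
    Regulation,
    RegulatoryModel,
    Terminator,
    TranscriptionUnit,
)

__all__ = ["SynthParams", "GroundTruthLedger", "SynthParamsError", "generate_model"]


class SynthParamsError(ValueError):
    """Infeasible generator parameters."""


@dataclass
class SynthParams:
    """Study conditions for the synthetic model.

    Defaults sketch a small bacterium-like regulatory system: mean operon
    size around 2, regulons of half a dozen promoters, activation and
    repression roughly balanced with a small dual and unknown remainder,
    and a modest metabolic layer with a couple of ubiquitous hub
    metabolites.
    """

    seed: int = 0
    n_genes: int = 200
    n_tfs: int = 15
    n_sigma: int = 3
    operon_size_mean: float = 2.0
    targets_per_tf_mean: float = 6.0
    p_activation: float = 0.45
    p_inhibition: float = 0.40
    p_dual: float = 0.05
    f_attenuation: float = 0.05
    f_translational: float = 0.08
    f_allosteric_rnap: float = 0.02
    n_compounds: int = 40
    n_reactions: int = 30
    f_reversible: float = 0.2
    n_enzyme_modulations: int = 25
    f_physiological: float = 0.5
    hub_compound_count: int = 2
    hub_degree: int = 12
    # fraction of TFs acting through a ligand-bound complex / modified form
    f_tf_complex: float = 0.3
    f_tf_modified: float = 0.2

    def validate(self) -> None:
        fracs = {
            "p_activation": self.p_activation,
            "p_inhibition": self.p_inhibition,
            "p_dual": self.p_dual,
            "f_attenuation": self.f_attenuation,
            "f_translational": self.f_translational,
            "f_allosteric_rnap": self.f_allosteric_rnap,
            "f_reversible": self.f_reversible,
            "f_physiological": self.f_physiological,
            "f_tf_complex": self.f_tf_complex,
            "f_tf_modified": self.f_tf_modified,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise SynthParamsError(f"{name} must be in [0, 1], got {v}")
        if self.p_activation + self.p_inhibition + self.p_dual > 1.0 + 1e-12:
            raise SynthParamsError("p_activation + p_inhibition + p_dual must be <= 1")
        for name in ("n_genes", "n_tfs", "n_sigma", "n_compounds", "n_reactions",
                     "n_enzyme_modulations", "hub_compound_count", "hub_degree"):
            if getattr(self, name) < 0:
                raise SynthParamsError(f"{name} must be non-negative")
        if self.n_genes <= 0:
            raise SynthParamsError("n_genes must be positive")
        if self.operon_size_mean < 1.0:
            raise SynthParamsError("operon_size_mean must be >= 1")
        if self.targets_per_tf_mean < 1.0:
            raise SynthParamsError("targets_per_tf_mean must be >= 1")
        n_srna = _n_srna(self)
        if self.n_tfs + self.n_sigma + n_srna > self.n_genes:
            raise SynthParamsError("n_tfs + n_sigma + sRNA genes exceed n_genes")
        if self.hub_compound_count > 0 and self.n_reactions < self.hub_degree:
            raise SynthParamsError("hub_degree exceeds n_reactions; hubs cannot be wired")
        if self.hub_compound_count >= self.n_compounds and self.hub_compound_count > 0:
            raise SynthParamsError("hub_compound_count must leave non-hub compounds")


def _n_srna(params: SynthParams) -> int:
    return max(2, params.n_genes // 100) if params.f_translational > 0 else 0


@dataclass
class GroundTruthLedger:
    """Construction-time bookkeeping mirroring the model-statistics fields."""

    counts: dict = field(default_factory=dict)
    genes_with_regulator: set = field(default_factory=set)
    regulator_categories: dict = field(default_factory=dict)  # regulator id -> category
    tf_targets: dict = field(default_factory=dict)  # regulator gene -> set of target genes
    per_gene_regulators: dict = field(default_factory=dict)  # gene -> set of regulator genes
    enzymes_modulated: set = field(default_factory=set)
    enzymes_modulated_physiological: set = field(default_factory=set)
    enzyme_modulators: set = field(default_factory=set)
    enzyme_modulators_physiological: set = field(default_factory=set)
    hub_compound_ids: list = field(default_factory=list)
    n_genes: int = 0

    def expected_stats(self) -> ModelStats:
        c = self.counts
        cats = list(self.regulator_categories.values())
        return ModelStats(
            transcriptional_regulation=c.get(TF_BINDING, 0)
            + c.get(ALLOSTERIC_RNAP, 0)
            + c.get(ATTENUATION, 0),
            tf_binding=c.get(TF_BINDING, 0),
            allosteric_rnap=c.get(ALLOSTERIC_RNAP, 0),
            attenuation=c.get(ATTENUATION, 0),
            translational_regulation=c.get(TRANSLATION, 0),
            translational_protein_mediated=c.get("protein-mediated", 0),
            translational_rna_mediated=c.get("rna-mediated", 0),
            translational_compound_mediated=c.get("compound-mediated", 0),
            enzyme_modulation=c.get(ENZYME_ACTIVITY, 0),
            enzyme_modulation_physiological=c.get("enzyme-activity-physiological", 0),
            genes_with_regulator=len(self.genes_with_regulator),
            genes_with_regulator_fraction=(
                len(self.genes_with_regulator) / self.n_genes if self.n_genes else 0.0
            ),
            regulators_total=len(cats),
            regulators_protein=sum(1 for x in cats if x == "protein"),
            regulators_rna=sum(1 for x in cats if x == "rna"),
            regulators_small_molecule=sum(1 for x in cats if x == "small-molecule"),
            enzymes_modulated=len(self.enzymes_modulated),
            enzymes_modulated_physiological=len(self.enzymes_modulated_physiological),
            enzyme_modulators=len(self.enzyme_modulators),
            enzyme_modulators_physiological=len(self.enzyme_modulators_physiological),
        )

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "genes_with_regulator": sorted(self.genes_with_regulator),
            "regulator_categories": dict(sorted(self.regulator_categories.items())),
            "tf_targets": {k: sorted(v) for k, v in sorted(self.tf_targets.items())},
            "per_gene_regulators": {k: sorted(v) for k, v in sorted(self.per_gene_regulators.items())},
            "enzymes_modulated": sorted(self.enzymes_modulated),
            "enzymes_modulated_physiological": sorted(self.enzymes_modulated_physiological),
            "enzyme_modulators": sorted(self.enzyme_modulators),
            "enzyme_modulators_physiological": sorted(self.enzyme_modulators_physiological),
            "hub_compound_ids": list(self.hub_compound_ids),
            "n_genes": self.n_genes,
        }


# named substreams of the master seed; appending new streams never
# perturbs existing ones
_STREAMS = {
    "operons": 1,
    "sigma": 2,
    "tf": 3,
    "attenuation": 4,
    "translation": 5,
    "reactions": 6,
    "modulation": 7,
    "enzymes": 8,
}


def _rng(params: SynthParams, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) % (2**31), _STREAMS[stream]])


def _draw_mode(rng: np.random.Generator, params: SynthParams) -> str:
    p_unknown = max(0.0, 1.0 - params.p_activation - params.p_inhibition - params.p_dual)
    return str(
        rng.choice(
            ["+", "-", "dual", "unknown"],
            p=[params.p_activation, params.p_inhibition, params.p_dual, p_unknown],
        )
    )


def generate_model(params: SynthParams) -> tuple[RegulatoryModel, GroundTruthLedger]:
    """Generate a valid model and its construction-time ground truth."""
    params.validate()
    model = RegulatoryModel()
    ledger = GroundTruthLedger(n_genes=params.n_genes)
    width = max(4, len(str(params.n_genes)))

    # genes and their primary products ----------------------------------
    gene_ids = [f"g{i:0{width}d}" for i in range(1, params.n_genes + 1)]
    n_srna = _n_srna(params)
    # role assignment by position keeps draws out of it (stable streams)
    sigma_genes = gene_ids[: params.n_sigma]
    tf_genes = gene_ids[params.n_sigma : params.n_sigma + params.n_tfs]
    srna_genes = gene_ids[params.n_sigma + params.n_tfs : params.n_sigma + params.n_tfs + n_srna]
    for g in gene_ids:
        kind = "rna" if g in srna_genes else "polypeptide"
        pid = f"p_{g}"
        model.genes[g] = Gene(id=g, name=g, product_id=pid)
        model.products[pid] = Product(id=pid, kind=kind, gene_ids=[g])

    # operon structure ---------------------------------------------------
    rng = _rng(params, "operons")
    p_geom = 1.0 / params.operon_size_mean
    tus: list[TranscriptionUnit] = []
    i = 0
    while i < params.n_genes:
        size = int(rng.geometric(p_geom))
        size = max(1, min(size, params.n_genes - i))
        tu_id = f"tu{len(tus) + 1:0{width}d}"
        prom_id = f"pm{len(tus) + 1:0{width}d}"
        tu = TranscriptionUnit(id=tu_id, gene_ids=gene_ids[i : i + size], promoter_id=prom_id)
        tus.append(tu)
        model.transcription_units[tu_id] = tu
        model.promoters[prom_id] = Promoter(id=prom_id, tu_id=tu_id)
        i += size

    # sigma factor assignment -------------------------------------------
    rng = _rng(params, "sigma")
    if sigma_genes:
        sigma_products = [f"p_{g}" for g in sigma_genes]
        for tu in tus:
            model.promoters[tu.promoter_id].sigma_factor_id = str(rng.choice(sigma_products))

    # helper for ledger bookkeeping on expression regulations -----------
    def record_expression(reg: Regulation, regulator_genes_known: list[str],
                          target_genes: list[str], category: str, transcriptional: bool) -> None:
        ledger.counts[reg.reg_class] = ledger.counts.get(reg.reg_class, 0) + 1
        if reg.reg_class == TRANSLATION and reg.sub_class:
            ledger.counts[reg.sub_class] = ledger.counts.get(reg.sub_class, 0) + 1
        ledger.genes_with_regulator.update(target_genes)
        ledger.regulator_categories.setdefault(reg.regulator_id, category)
        if transcriptional:
            for rg in regulator_genes_known:
                ledger.tf_targets.setdefault(rg, set()).update(target_genes)
        for tg in target_genes:
            ledger.per_gene_regulators.setdefault(tg, set()).update(regulator_genes_known)

    # transcription factor regulons -------------------------------------
    rng = _rng(params, "tf")
    compounds = [Compound(id=f"c{i:04d}", name=f"compound {i}") for i in range(1, params.n_compounds + 1)]
    for c in compounds:
        model.compounds[c.id] = c
    reg_no = 0
    tf_entity: dict[str, str] = {}
    for tf in tf_genes:
        base = f"p_{tf}"
        u = rng.random()
        if u < params.f_tf_complex and compounds:
            ligand = str(rng.choice([c.id for c in compounds]))
            eid = f"cx_{tf}"
            model.products[eid] = Product(
                id=eid, kind="complex", component_ids=[base, ligand], ligand_ids=[ligand]
            )
        elif u < params.f_tf_complex + params.f_tf_modified:
            eid = f"mod_{tf}"
            model.products[eid] = Product(id=eid, kind="modified-form", unmodified_form_id=base)
        else:
            eid = base
        tf_entity[tf] = eid
        n_targets = max(1, int(rng.poisson(params.targets_per_tf_mean)))
        n_targets = min(n_targets, len(tus))
        chosen = rng.choice(len(tus), size=n_targets, replace=False)
        for tui in sorted(int(x) for x in chosen):
            tu = tus[tui]
            reg_no += 1
            cls = ALLOSTERIC_RNAP if rng.random() < params.f_allosteric_rnap else TF_BINDING
            reg = Regulation(
                id=f"r{reg_no:05d}",
                reg_class=cls,
                regulator_id=tf_entity[tf],
                regulated_entity_id=tu.promoter_id,
                mode=_draw_mode(rng, params),
            )
            model.regulations[reg.id] = reg
            record_expression(reg, [tf], list(tu.gene_ids), "protein", transcriptional=True)

    n_expr = reg_no

    # attenuation --------------------------------------------------------
    rng = _rng(params, "attenuation")
    multi_tus = [tu for tu in tus if len(tu.gene_ids) >= 2]
    n_att = round(params.f_attenuation * n_expr) if multi_tus and tf_genes else 0
    term_no = 0
    for _ in range(n_att):
        tu = multi_tus[int(rng.integers(len(multi_tus)))]
        term_no += 1
        site = int(rng.integers(1, len(tu.gene_ids)))
        term = Terminator(id=f"t{term_no:04d}", tu_id=tu.id, site_index=site)
        model.terminators[term.id] = term
        tu.terminator_ids.append(term.id)
        tf = tf_genes[int(rng.integers(len(tf_genes)))]
        reg_no += 1
        reg = Regulation(
            id=f"r{reg_no:05d}",
            reg_class=ATTENUATION,
            regulator_id=tf_entity[tf],
            regulated_entity_id=term.id,
            mode=_draw_mode(rng, params),
            sub_class=str(rng.choice(["ribosome-mediated", "protein-mediated", "rna-mediated"])),
        )
        model.regulations[reg.id] = reg
        downstream = list(tu.gene_ids[site:])
        record_expression(reg, [tf], downstream, "protein", transcriptional=True)

    # translational regulation ------------------------------------------
    rng = _rng(params, "translation")
    n_tr = round(params.f_translational * n_expr)
    for _ in range(n_tr):
        sub = str(rng.choice(["protein-mediated", "rna-mediated", "compound-mediated"]))
        if sub == "protein-mediated" and tf_genes:
            tf = tf_genes[int(rng.integers(len(tf_genes)))]
            regulator, reg_genes, cat = tf_entity[tf], [tf], "protein"
        elif sub == "rna-mediated" and srna_genes:
            sg = srna_genes[int(rng.integers(len(srna_genes)))]
            regulator, reg_genes, cat = f"p_{sg}", [sg], "rna"
        else:
            sub = "compound-mediated"
            regulator = compounds[int(rng.integers(len(compounds)))].id
            reg_genes, cat = [], "small-molecule"
        if rng.random() < 0.7:
            g = gene_ids[int(rng.integers(len(gene_ids)))]
            target_id, targets = g, [g]
        else:
            tu = tus[int(rng.integers(len(tus)))]
            target_id, targets = tu.id, list(tu.gene_ids)
        reg_no += 1
        reg = Regulation(
            id=f"r{reg_no:05d}",
            reg_class=TRANSLATION,
            regulator_id=regulator,
            regulated_entity_id=target_id,
            mode=_draw_mode(rng, params),
            sub_class=sub,
            mechanism=str(rng.choice(["ribosome-blocking", "mrna-degradation", "both"])),
        )
        model.regulations[reg.id] = reg
        record_expression(reg, reg_genes, targets, cat, transcriptional=False)

    # enzymes and reactions ----------------------------------------------
    rng = _rng(params, "enzymes")
    n_enz = max(1, params.n_genes // 10)
    non_reg = [g for g in gene_ids if g not in sigma_genes and g not in tf_genes and g not in srna_genes]
    pool = non_reg if len(non_reg) >= n_enz else gene_ids
    enz_idx = rng.choice(len(pool), size=min(n_enz, len(pool)), replace=False)
    enzyme_products = sorted(f"p_{pool[int(i)]}" for i in enz_idx)

    rng = _rng(params, "reactions")
    hub_ids = [c.id for c in compounds[: params.hub_compound_count]]
    ledger.hub_compound_ids = list(hub_ids)
    free = [c.id for c in compounds[params.hub_compound_count :]]
    rxns: list[Reaction] = []
    for i in range(1, params.n_reactions + 1):
        if len(free) < 2:
            break
        n_r = int(rng.integers(1, 3))
        n_p = int(rng.integers(1, 3))
        picked = rng.choice(len(free), size=min(n_r + n_p, len(free)), replace=False)
        picked = [free[int(x)] for x in picked]
        reactants, products = picked[:n_r] or picked[:1], picked[n_r:] or picked[-1:]
        if not reactants or not products:
            continue
        rxn = Reaction(
            id=f"rx{i:04d}",
            reactant_ids=list(reactants),
            product_ids=list(products),
            enzyme_ids=[str(rng.choice(enzyme_products))] if enzyme_products and rng.random() < 0.9 else [],
            reversible=bool(rng.random() < params.f_reversible),
        )
        rxns.append(rxn)
        model.reactions[rxn.id] = rxn
    # wire each hub compound into exactly hub_degree reactions
    for h_i, hub in enumerate(hub_ids):
        if not rxns:
            break
        chosen = rng.choice(len(rxns), size=min(params.hub_degree, len(rxns)), replace=False)
        for j, ri in enumerate(sorted(int(x) for x in chosen)):
            rxn = rxns[ri]
            if j % 2 == 0:
                rxn.reactant_ids.append(hub)
            else:
                rxn.product_ids.append(hub)

    # substrate-level enzyme modulation ----------------------------------
    rng = _rng(params, "modulation")
    rxns_with_enzyme = [r for r in rxns if r.enzyme_ids]
    for i in range(params.n_enzyme_modulations):
        if not enzyme_products or not compounds:
            break
        modulator = compounds[int(rng.integers(len(compounds)))].id
        if rxns_with_enzyme and rng.random() < 0.3:
            rxn = rxns_with_enzyme[int(rng.integers(len(rxns_with_enzyme)))]
            target_id, enzymes = rxn.id, set(rxn.enzyme_ids)
        else:
            enz = str(rng.choice(enzyme_products))
            target_id, enzymes = enz, {enz}
        p_act = params.p_activation + params.p_inhibition
        mode = "+" if (p_act > 0 and rng.random() < params.p_activation / p_act) else "-"
        phys = bool(rng.random() < params.f_physiological)
        reg_no += 1
        reg = Regulation(
            id=f"r{reg_no:05d}",
            reg_class=ENZYME_ACTIVITY,
            regulator_id=modulator,
            regulated_entity_id=target_id,
            mode=mode,
            mechanism=str(rng.choice(["allosteric", "competitive"])),
            physiologically_relevant=phys,
        )
        model.regulations[reg.id] = reg
        ledger.counts[ENZYME_ACTIVITY] = ledger.counts.get(ENZYME_ACTIVITY, 0) + 1
        ledger.enzymes_modulated |= enzymes
        ledger.enzyme_modulators.add(modulator)
        if phys:
            ledger.counts["enzyme-activity-physiological"] = (
                ledger.counts.get("enzyme-activity-physiological", 0) + 1
            )
            ledger.enzymes_modulated_physiological |= enzymes
            ledger.enzyme_modulators_physiological.add(modulator)

    model.reindex()
    return model, ledger
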