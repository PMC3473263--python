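import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from regnet.model import (
    Compound,
    Gene,
    Product,
    Promoter,
    Reaction,
    Regulation,
    RegulatoryModel,
    Terminator,
    TranscriptionUnit,
)
from regnet.synth import SynthParams, generate_model


def build_toy_model() -> RegulatoryModel:
    """A small consistent model exercising every entity kind.

    Operon tu1 = [g1, g2, g3] with promoter pm1 and an internal terminator
    after g1; TF gene gt acts on pm1 through a ligand-bound homodimer
    complex; sigma gene gs recognizes pm1; an sRNA gene gr regulates g3
    translation; enzyme gene ge catalyzes an irreversible reaction that is
    feedback-inhibited by its product compound.
    """
    m = RegulatoryModel()
    for gid in ("g1", "g2", "g3", "gt", "gs", "gr", "ge"):
        kind = "rna" if gid == "gr" else "polypeptide"
        m.genes[gid] = Gene(id=gid, name=gid, product_id=f"p_{gid}")
        m.products[f"p_{gid}"] = Product(id=f"p_{gid}", kind=kind, gene_ids=[gid])
    m.compounds["trp"] = Compound(id="trp", name="effector ligand")
    m.compounds["sub"] = Compound(id="sub", name="substrate")
    m.compounds["prod"] = Compound(id="prod", name="pathway product")
    # TF acts as a ligand-bound dimer: modified form of a homodimer complex
    m.products["dim_gt"] = Product(id="dim_gt", kind="complex", component_ids=["p_gt", "p_gt"])
    m.products["holo_gt"] = Product(
        id="holo_gt", kind="complex", component_ids=["dim_gt", "trp"], ligand_ids=["trp"]
    )
    m.transcription_units["tu1"] = TranscriptionUnit(
        id="tu1", gene_ids=["g1", "g2", "g3"], promoter_id="pm1", terminator_ids=["term1"]
    )
    m.transcription_units["tu2"] = TranscriptionUnit(id="tu2", gene_ids=["gt"], promoter_id="pm2")
    m.promoters["pm1"] = Promoter(id="pm1", tu_id="tu1", sigma_factor_id="p_gs")
    m.promoters["pm2"] = Promoter(id="pm2", tu_id="tu2", sigma_factor_id="p_gs")
    m.terminators["term1"] = Terminator(id="term1", tu_id="tu1", site_index=1)
    m.reactions["rx1"] = Reaction(
        id="rx1", reactant_ids=["sub"], product_ids=["prod"], enzyme_ids=["p_ge"], reversible=False
    )
    m.regulations["reg_tf"] = Regulation(
        id="reg_tf",
        reg_class="transcription-factor-binding",
        regulator_id="holo_gt",
        regulated_entity_id="pm1",
        mode="-",
    )
    m.regulations["reg_att"] = Regulation(
        id="reg_att",
        reg_class="transcriptional-attenuation",
        regulator_id="p_gt",
        regulated_entity_id="term1",
        mode="-",
        sub_class="ribosome-mediated",
    )
    m.regulations["reg_tl"] = Regulation(
        id="reg_tl",
        reg_class="regulation-of-translation",
        regulator_id="p_gr",
        regulated_entity_id="g3",
        mode="+",
        sub_class="rna-mediated",
        mechanism="ribosome-blocking",
    )
    m.regulations["reg_enz"] = Regulation(
        id="reg_enz",
        reg_class="regulation-of-enzyme-activity",
        regulator_id="prod",
        regulated_entity_id="p_ge",
        mode="-",
        mechanism="allosteric",
        physiologically_relevant=True,
    )
    return m.reindex()


@pytest.fixture
def toy_model() -> RegulatoryModel:
    return build_toy_model()


@pytest.fixture(scope="session")
def small_synth():
    """A mid-sized generated model with its ground-truth ledger."""
    params = SynthParams(seed=11, n_genes=80, n_tfs=8, n_sigma=2)
    return generate_model(params)
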