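"""Reading and writing the RegJSON model dialect and XGMML networks.

RegJSON is a plain-JSON serialization of the regulatory model: one document
with a ``format_version`` and one array per entity kind, each element
carrying exactly the fields of the corresponding domain type in snake_case.
The writer is canonical — arrays sorted by id, keys in fixed order, absent
optionals omitted — so equal models always serialize to byte-equal files.

XGMML export targets Cytoscape: one ``<graph directed="1">`` with one node
per gene and one edge per regulatory edge, the regulatory effect carried in
a string attribute named ``mode`` (activation / inhibition / dual /
unknown) and the contributing regulation ids in a list attribute named
``provenance``.  Layout coordinates, when given, go into ``<graphics>``
elements.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree as ET

from .model import (
    BindingSite,
    Compound,
    Gene,
    Product,
    Promoter,
    Reaction,
    Regulation,
    RegulatoryModel,
    Terminator,
    TranscriptionUnit,
    validate_model,
)

__all__ = [
    "RegJSONError",
    "ModelValidationError",
    "XGMMLError",
    "read_model",
    "write_model",
    "model_to_document",
    "model_from_document",
    "write_xgmml",
    "read_xgmml",
]

FORMAT_VERSION = "1.0"
XGMML_NS = "http://www.cs.rpi.edu/XGMML"

_TOP_KEYS = (
    "genes",
    "transcription_units",
    "promoters",
    "terminators",
    "products",
    "compounds",
    "reactions",
    "regulations",
)

# (json key, default considered "absent") in canonical output order
_FIELD_ORDER: dict[str, list[str]] = {
    "genes": ["id", "name", "product_id"],
    "transcription_units": ["id", "gene_ids", "promoter_id", "terminator_ids"],
    "promoters": ["id", "tu_id", "sigma_factor_id"],
    "terminators": ["id", "tu_id", "site_index"],
    "products": ["id", "kind", "gene_ids", "component_ids", "unmodified_form_id", "ligand_ids"],
    "compounds": ["id", "name"],
    "reactions": ["id", "reactant_ids", "product_ids", "enzyme_ids", "reversible"],
    "regulations": [
        "id",
        "reg_class",
        "regulator_id",
        "regulated_entity_id",
        "mode",
        "sub_class",
        "mechanism",
        "physiologically_relevant",
        "binding_site",
    ],
}

_TYPES = {
    "genes": Gene,
    "transcription_units": TranscriptionUnit,
    "promoters": Promoter,
    "terminators": Terminator,
    "products": Product,
    "compounds": Compound,
    "reactions": Reaction,
    "regulations": Regulation,
}

_MODEL_ATTR = {
    "genes": "genes",
    "transcription_units": "transcription_units",
    "promoters": "promoters",
    "terminators": "terminators",
    "products": "products",
    "compounds": "compounds",
    "reactions": "reactions",
    "regulations": "regulations",
}


class RegJSONError(Exception):
    """Malformed RegJSON document."""


class ModelValidationError(Exception):
    """A parsed model failed structural validation."""

    def __init__(self, report):
        self.report = report
        super().__init__(report.summary())


class XGMMLError(Exception):
    """Malformed or unsupported XGMML document."""


# ---------------------------------------------------------------------------
# RegJSON


def _entity_to_obj(entity, key: str) -> dict:
    obj = {}
    for f in _FIELD_ORDER[key]:
        v = getattr(entity, f)
        if v is None:
            continue
        if isinstance(v, list) and not v:
            continue
        if f == "binding_site":
            v = {"position": v.position, "description": v.description}
        obj[f] = v
    return obj


def model_to_document(model: RegulatoryModel) -> dict:
    doc: dict = {"format_version": FORMAT_VERSION}
    for key in _TOP_KEYS:
        table = getattr(model, _MODEL_ATTR[key])
        doc[key] = [_entity_to_obj(table[eid], key) for eid in sorted(table)]
    return doc


def model_from_document(doc: dict) -> RegulatoryModel:
    if not isinstance(doc, dict):
        raise RegJSONError("top-level JSON value must be an object")
    unknown = set(doc) - set(_TOP_KEYS) - {"format_version"}
    if unknown:
        raise RegJSONError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    model = RegulatoryModel()
    for key in _TOP_KEYS:
        cls = _TYPES[key]
        table = getattr(model, _MODEL_ATTR[key])
        for obj in doc.get(key, []):
            if not isinstance(obj, dict):
                raise RegJSONError(f"elements of {key!r} must be objects")
            bad = set(obj) - set(_FIELD_ORDER[key])
            if bad:
                raise RegJSONError(
                    f"unknown field(s) {', '.join(sorted(bad))} in {key!r} entry {obj.get('id')!r}"
                )
            if "id" not in obj:
                raise RegJSONError(f"entry in {key!r} lacks an id")
            kwargs = dict(obj)
            if key == "regulations" and "binding_site" in kwargs:
                bs = kwargs["binding_site"]
                kwargs["binding_site"] = BindingSite(
                    position=bs.get("position", 0), description=bs.get("description", "")
                )
            entity = cls(**kwargs)
            if entity.id in table:
                raise RegJSONError(f"duplicate id {entity.id!r} in {key!r}")
            table[entity.id] = entity
    return model.reindex()


def write_model(model: RegulatoryModel, path) -> None:
    """Canonical serialization: equal models give byte-identical files."""
    doc = model_to_document(model)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_model(path, validate: bool = True) -> RegulatoryModel:
    """Parse a RegJSON file, rebuild indices, and (by default) validate.

    A non-empty validation error list aborts with
    :class:`ModelValidationError` carrying the full report.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise RegJSONError(f"{path}: JSON parse error at line {e.lineno}: {e.msg}") from e
    model = model_from_document(doc)
    if validate:
        report = validate_model(model)
        if not report.ok:
            raise ModelValidationError(report)
    return model


# ---------------------------------------------------------------------------
# XGMML


def write_xgmml(network, layout=None, path=None, label: str = "regulatory-network"):
    """Write a gene network as XGMML 1.0 (directed, Cytoscape-compatible).

    Numeric node ids are assigned in sorted gene-id order; the gene id is
    carried in the node ``label``, which is what Cytoscape keys on.  If
    ``layout`` is given its coordinates are embedded as ``<graphics>``.
    """
    nodes = sorted(network.nodes())
    if not nodes:
        raise XGMMLError("cannot export an empty network")
    if layout is not None:
        missing = set(layout.coordinates) - set(nodes)
        if missing:
            raise XGMMLError(
                f"layout covers node(s) absent from network: {', '.join(sorted(missing))}"
            )
    idx = {g: str(i) for i, g in enumerate(nodes)}
    root = ET.Element("graph", {"xmlns": XGMML_NS, "directed": "1", "label": label})
    for g in nodes:
        node = ET.SubElement(root, "node", {"id": idx[g], "label": g})
        if layout is not None and g in layout.coordinates:
            x, y = layout.coordinates[g]
            ET.SubElement(node, "graphics", {"x": repr(float(x)), "y": repr(float(y))})
    for src, tgt in sorted(network.edges()):
        mode, provenance = network.edge_data(src, tgt)
        edge = ET.SubElement(
            root,
            "edge",
            {"source": idx[src], "target": idx[tgt], "label": f"{src} ({mode}) {tgt}"},
        )
        ET.SubElement(edge, "att", {"name": "mode", "type": "string", "value": mode})
        plist = ET.SubElement(edge, "att", {"name": "provenance", "type": "list"})
        for pid in sorted(provenance):
            ET.SubElement(plist, "att", {"name": "provenance", "type": "string", "value": pid})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_xgmml(path):
    """Read a network written by :func:`write_xgmml` (or equivalent dialect)."""
    from .network import EDGE_MODES, GeneNetwork

    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise XGMMLError(f"{path}: XML parse error: {e}") from e
    root = tree.getroot()
    if _strip_ns(root.tag) != "graph":
        raise XGMMLError("root element is not <graph>")
    if root.get("directed") != "1":
        raise XGMMLError("only directed graphs are supported (directed=\"1\")")
    net = GeneNetwork()
    labels: dict[str, str] = {}
    for el in root:
        tag = _strip_ns(el.tag)
        if tag == "node":
            nid, label = el.get("id"), el.get("label")
            if nid is None or label is None:
                raise XGMMLError("node lacks id or label")
            labels[nid] = label
            net.add_node(label)
    for el in root:
        if _strip_ns(el.tag) != "edge":
            continue
        src, tgt = el.get("source"), el.get("target")
        if src not in labels or tgt not in labels:
            raise XGMMLError(f"edge references unknown node id {src!r} or {tgt!r}")
        mode: Optional[str] = None
        provenance: set[str] = set()
        for att in el:
            if _strip_ns(att.tag) != "att":
                continue
            if att.get("name") == "mode":
                mode = att.get("value")
            elif att.get("name") == "provenance":
                for sub in att:
                    v = sub.get("value")
                    if v:
                        provenance.add(v)
        if mode not in EDGE_MODES:
            raise XGMMLError(f"edge {src}->{tgt} has unknown mode {mode!r}")
        net.add_edge(labels[src], labels[tgt], mode, provenance or {"imported"})
    return net
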