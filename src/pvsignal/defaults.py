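"""Shipped default query definitions.

The package ships the GERD-like-symptoms MedDRA query (36 preferred terms)
and the two incretin-based drug classes as editable YAML under
``pvsignal/data``; users can point the loaders at their own files for other
drug-event questions.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .reports import DrugClassDef, PTSet

GLP1_CLASS_NAME = "GLP-1-RAs"
DPP4_CLASS_NAME = "DPP-4-Is"


def _data_path(name: str):
    return resources.files("pvsignal.data") / name


def gerd_pt_set() -> PTSet:
    """The 36-PT 'GERD-like symptoms' query."""
    with resources.as_file(_data_path("gerd_pt_set.yaml")) as path:
        return PTSet.from_yaml(path)


def drug_classes(path=None) -> dict[str, DrugClassDef]:
    """Drug classes keyed by class name (default: the two incretin classes)."""
    if path is None:
        with resources.as_file(_data_path("drug_classes.yaml")) as p:
            doc = yaml.safe_load(p.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return {
        name: DrugClassDef(name, frozenset(members)) for name, members in doc.items()
    }


def glp1_class() -> DrugClassDef:
    return drug_classes()[GLP1_CLASS_NAME]


def dpp4_class() -> DrugClassDef:
    return drug_classes()[DPP4_CLASS_NAME]
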