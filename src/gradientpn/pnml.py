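"""PNML (Petri Net Markup Language) reader/writer for PTA-nets.

Standard PT-net PNML (2009 grammar): places carry ``initialMarking``, arcs
carry ``inscription`` weights.  Activator arcs are not part of the PT-net
grammar, so they are encoded as ordinary arcs annotated with a
tool-specific element::

    <arc id="..." source="p" target="t">
      <toolspecific tool="gradientpn" version="0.1">
        <arctype>activator</arctype>
      </toolspecific>
    </arc>

The reader accepts files written here and plain PT-net PNML from other
tools (activator annotations are simply absent there).  Optional
human-readable labels (e.g. ``x1`` -> "cell 1") are embedded as PNML
``<name>`` labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from lxml import etree

from .errors import InputError
from .pta import Marking, PTANet

__all__ = ["write_pnml", "read_pnml"]

_NS = "http://www.pnml.org/version-2009/grammar/pnml"
_PTNET = "http://www.pnml.org/version-2009/grammar/ptnet"
_TOOL = "gradientpn"


def _text_child(parent, tag: str, text: str) -> None:
    el = etree.SubElement(parent, f"{{{_NS}}}{tag}")
    etree.SubElement(el, f"{{{_NS}}}text").text = text


def write_pnml(
    net: PTANet,
    path: str | Path,
    net_id: str = "net1",
    labels: Mapping[str, str] | None = None,
) -> None:
    """Serialize a PTA-net to a PNML file (deterministic element order)."""
    labels = labels or {}
    root = etree.Element(f"{{{_NS}}}pnml", nsmap={None: _NS})
    net_el = etree.SubElement(root, f"{{{_NS}}}net", id=net_id, type=_PTNET)
    page = etree.SubElement(net_el, f"{{{_NS}}}page", id="page1")
    for p in sorted(net.places):
        pl = etree.SubElement(page, f"{{{_NS}}}place", id=p)
        if p in labels:
            _text_child(pl, "name", labels[p])
        tokens = net.initial_marking[p]
        if tokens:
            _text_child(pl, "initialMarking", str(tokens))
    for t in sorted(net.transitions):
        tr = etree.SubElement(page, f"{{{_NS}}}transition", id=t)
        if t in labels:
            _text_child(tr, "name", labels[t])
    counter = 0
    for src, dst in sorted(net.weight):
        counter += 1
        arc = etree.SubElement(
            page, f"{{{_NS}}}arc", id=f"a{counter}", source=src, target=dst
        )
        w = net.weight[(src, dst)]
        if w != 1:
            _text_child(arc, "inscription", str(w))
    for place, trans in sorted(net.activators):
        counter += 1
        arc = etree.SubElement(
            page, f"{{{_NS}}}arc", id=f"a{counter}", source=place, target=trans
        )
        tool = etree.SubElement(
            arc, f"{{{_NS}}}toolspecific", tool=_TOOL, version="0.1"
        )
        etree.SubElement(tool, f"{{{_NS}}}arctype").text = "activator"
    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _label_text(el, tag: str) -> str | None:
    for child in el:
        if _local(child.tag) == tag:
            for sub in child:
                if _local(sub.tag) == "text":
                    return sub.text
    return None


def read_pnml(path: str | Path) -> tuple[PTANet, dict[str, str]]:
    """Parse a PNML file into a PTA-net and a label map."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise InputError(f"cannot parse PNML file {path}: {exc}") from exc
    root = tree.getroot()
    places: set[str] = set()
    transitions: set[str] = set()
    weight: dict[tuple[str, str], int] = {}
    activators: set[tuple[str, str]] = set()
    marking: dict[str, int] = {}
    labels: dict[str, str] = {}
    arcs: list[tuple[str, str, int, bool]] = []
    for el in root.iter():
        kind = _local(el.tag)
        if kind == "place":
            pid = el.get("id")
            places.add(pid)
            name = _label_text(el, "name")
            if name:
                labels[pid] = name
            tokens = _label_text(el, "initialMarking")
            if tokens:
                marking[pid] = int(tokens)
        elif kind == "transition":
            tid = el.get("id")
            transitions.add(tid)
            name = _label_text(el, "name")
            if name:
                labels[tid] = name
        elif kind == "arc":
            src, dst = el.get("source"), el.get("target")
            if src is None or dst is None:
                raise InputError("arc without source/target")
            inscription = _label_text(el, "inscription")
            w = int(inscription) if inscription else 1
            is_activator = False
            for child in el:
                if _local(child.tag) == "toolspecific" and el is not None:
                    for sub in child.iter():
                        if _local(sub.tag) == "arctype" and (sub.text or "").strip() == "activator":
                            is_activator = True
            arcs.append((src, dst, w, is_activator))
    for src, dst, w, is_act in arcs:
        if is_act:
            activators.add((src, dst))
        else:
            weight[(src, dst)] = w
    net = PTANet(
        places=frozenset(places),
        transitions=frozenset(transitions),
        weight=weight,
        activators=frozenset(activators),
        initial_marking=Marking(marking),
    )
    return net, labels
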