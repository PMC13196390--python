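"""Readers and writers for every TSV/JSON dialect the pipeline touches.

Conventions
-----------
* Tab-separated, one header line, UTF-8.
* Missing intensity = empty cell or the literal ``NA`` (no numeric sentinel).
* List-valued cells use ``,`` between items; structured cells use ``:``
  between parts (e.g., a site is ``T:161`` on an edge, ``PROT:T:305`` on a
  feature).
* All writers are byte-stable: identical in-memory objects produce identical
  files, with no timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .model import FeatureAnnotation, IntensityMatrix, SampleDesign
from .network import (CausalEdge, CausalNetwork, SiteAnnotation,
                      validate_tf_targets)

logger = logging.getLogger("pepwire")

NA_VALUES = ["", "NA"]


# ---------------------------------------------------------------------------
# intensity matrices

def read_intensity_matrix(path: str | Path, layer: str, design: SampleDesign,
                          scale: str = "raw") -> IntensityMatrix:
    """Read a features x samples TSV (header ``feature_id`` then sample ids).

    Columns are reordered to the design's sample order.  An unknown or missing
    sample column and a duplicated feature id are hard errors.
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=NA_VALUES,
                        keep_default_na=False, float_precision="round_trip")
    if frame.columns[0] != "feature_id":
        raise FormatError(f"{path}: first column must be 'feature_id', "
                          f"got {frame.columns[0]!r}")
    sample_cols = list(frame.columns[1:])
    unknown = [c for c in sample_cols if c not in design.sample_ids]
    if unknown:
        raise FormatError(f"{path}: sample columns not in design: {unknown}")
    absent = [c for c in design.sample_ids if c not in sample_cols]
    if absent:
        raise FormatError(f"{path}: design samples missing from file: {absent}")
    if frame["feature_id"].duplicated().any():
        dupes = frame.loc[frame["feature_id"].duplicated(), "feature_id"].tolist()
        raise FormatError(f"{path}: duplicate feature ids: {dupes[:5]}")
    data = frame.set_index("feature_id")[list(design.sample_ids)].astype(float)
    data.index.name = "feature_id"
    return IntensityMatrix(layer=layer, data=data, design=design, scale=scale)


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    # %.17g round-trips every IEEE double exactly
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# causal network

def _format_edge_site(site: Optional[tuple[str, int]]) -> str:
    return "" if site is None else f"{site[0]}:{site[1]}"


def _parse_edge_site(cell: str, where: str) -> Optional[tuple[str, int]]:
    if not cell:
        return None
    parts = cell.split(":")
    if len(parts) != 2 or not parts[1].isdigit():
        raise FormatError(f"{where}: malformed site {cell!r} (expected RES:POS)")
    return (parts[0], int(parts[1]))


def write_causal_network(network: CausalNetwork, edges_path: str | Path,
                         nodes_path: str | Path) -> None:
    edge_rows = [
        {"source": e.source, "target": e.target, "sign": e.sign,
         "edge_type": e.edge_type, "site": _format_edge_site(e.site)}
        for e in sorted(network.edges(), key=lambda e: (e.source, e.target,
                                                        e.edge_type, str(e.site)))]
    pd.DataFrame(edge_rows, columns=["source", "target", "sign", "edge_type",
                                     "site"]).to_csv(edges_path, sep="\t", index=False)
    node_rows = []
    for node in network.nodes:
        node_rows.append({
            "node_id": node,
            "is_kinase": int(network.is_kinase(node)),
            "is_tf": int(network.is_tf(node)),
            "is_druggable": int(network.is_druggable(node)),
            "family_members": ",".join(network.family_members(node)),
        })
    pd.DataFrame(node_rows, columns=["node_id", "is_kinase", "is_tf",
                                     "is_druggable", "family_members"]
                 ).to_csv(nodes_path, sep="\t", index=False)


def read_causal_network(edges_path: str | Path,
                        nodes_path: str | Path) -> CausalNetwork:
    """Read a signed edge list plus its node-attribute table and validate."""
    nodes_frame = pd.read_csv(nodes_path, sep="\t", dtype=str,
                              keep_default_na=False)
    for col in ("node_id", "is_kinase", "is_tf", "is_druggable", "family_members"):
        if col not in nodes_frame.columns:
            raise FormatError(f"{nodes_path}: missing column {col!r}")
    nodes: dict[str, dict] = {}
    for _, row in nodes_frame.iterrows():
        members = tuple(m for m in row["family_members"].split(",") if m)
        nodes[row["node_id"]] = dict(
            is_kinase=row["is_kinase"] == "1", is_tf=row["is_tf"] == "1",
            is_druggable=row["is_druggable"] == "1", family_members=members)

    edges_frame = pd.read_csv(edges_path, sep="\t", dtype=str,
                              keep_default_na=False)
    for col in ("source", "target", "sign", "edge_type", "site"):
        if col not in edges_frame.columns:
            raise FormatError(f"{edges_path}: missing column {col!r}")
    edges = []
    for i, row in edges_frame.iterrows():
        where = f"{edges_path}:row {i + 2}"
        if row["sign"] not in ("1", "-1", "+1"):
            raise FormatError(f"{where}: sign must be +1 or -1, got {row['sign']!r}")
        for endpoint in (row["source"], row["target"]):
            if endpoint not in nodes:
                raise FormatError(f"{where}: dangling endpoint {endpoint!r}")
        edges.append(CausalEdge(row["source"], row["target"], int(row["sign"]),
                                row["edge_type"],
                                _parse_edge_site(row["site"], where)))
    return CausalNetwork.from_parts(nodes, edges)


# ---------------------------------------------------------------------------
# annotation tables

def write_site_annotations(sites: Sequence[SiteAnnotation], path: str | Path) -> None:
    rows = [{"protein_id": s.protein_id, "residue": s.residue,
             "position": s.position,
             "functional_effect": s.functional_effect or "",
             "upstream_kinases": ",".join(s.upstream_kinases)}
            for s in sorted(sites, key=lambda s: s.site)]
    pd.DataFrame(rows, columns=["protein_id", "residue", "position",
                                "functional_effect", "upstream_kinases"]
                 ).to_csv(path, sep="\t", index=False)


def read_site_annotations(path: str | Path) -> list[SiteAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for i, row in frame.iterrows():
        where = f"{path}:row {i + 2}"
        if not row["position"].isdigit():
            raise FormatError(f"{where}: position must be a positive integer")
        out.append(SiteAnnotation(
            protein_id=row["protein_id"], residue=row["residue"],
            position=int(row["position"]),
            functional_effect=row["functional_effect"] or None,
            upstream_kinases=tuple(k for k in row["upstream_kinases"].split(",") if k)))
    return out


def write_tf_targets(table: pd.DataFrame, path: str | Path) -> None:
    table.sort_values(["tf_id", "target_id"]).to_csv(path, sep="\t", index=False)


def read_tf_targets(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "target_id": str,
                                               "sign": int})
    return validate_tf_targets(frame)


def write_inhibitor_map(inhibitor_map: Mapping[str, frozenset[str]],
                        path: str | Path) -> None:
    rows = [{"treatment": t, "kinases": ",".join(sorted(ks))}
            for t, ks in sorted(inhibitor_map.items())]
    pd.DataFrame(rows, columns=["treatment", "kinases"]).to_csv(
        path, sep="\t", index=False)


def read_inhibitor_map(path: str | Path) -> dict[str, frozenset[str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, frozenset[str]] = {}
    for _, row in frame.iterrows():
        out[row["treatment"]] = frozenset(
            k for k in row["kinases"].split(",") if k)
    return out


def _format_feature_site(site) -> str:
    return "" if site is None else f"{site[0]}:{site[1]}:{site[2]}"


def write_feature_annotations(annotations: Sequence[FeatureAnnotation],
                              path: str | Path) -> None:
    rows = []
    for a in sorted(annotations, key=lambda a: a.feature_id):
        rows.append({
            "feature_id": a.feature_id,
            "feature_kind": a.feature_kind,
            "peptide_sequence": a.peptide_sequence or "",
            "source_proteins": ",".join(a.source_proteins),
            "site": _format_feature_site(a.site),
            "allele_binding": ";".join(f"{al}:{cl}" for al, cl in a.allele_binding),
            "immunogenicity": "" if a.immunogenicity is None else repr(a.immunogenicity),
        })
    pd.DataFrame(rows, columns=["feature_id", "feature_kind", "peptide_sequence",
                                "source_proteins", "site", "allele_binding",
                                "immunogenicity"]).to_csv(path, sep="\t", index=False)


def read_feature_annotations(path: str | Path) -> list[FeatureAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for i, row in frame.iterrows():
        where = f"{path}:row {i + 2}"
        site = None
        if row["site"]:
            parts = row["site"].split(":")
            if len(parts) != 3 or not parts[2].isdigit():
                raise FormatError(f"{where}: malformed site {row['site']!r}")
            site = (parts[0], parts[1], int(parts[2]))
        binding = []
        for token in (t for t in row["allele_binding"].split(";") if t):
            allele, _, cls = token.rpartition(":")
            binding.append((allele, cls))
        out.append(FeatureAnnotation(
            feature_id=row["feature_id"], feature_kind=row["feature_kind"],
            peptide_sequence=row["peptide_sequence"] or None,
            source_proteins=tuple(p for p in row["source_proteins"].split(",") if p),
            site=site, allele_binding=tuple(binding),
            immunogenicity=float(row["immunogenicity"]) if row["immunogenicity"] else None))
    return out


# ---------------------------------------------------------------------------
# presence lists / binder calls

def write_presence_counts(presence: Mapping[str, int], path: str | Path) -> None:
    rows = [{"peptide": p, "n_samples": n} for p, n in sorted(presence.items())]
    pd.DataFrame(rows, columns=["peptide", "n_samples"]).to_csv(
        path, sep="\t", index=False)


def read_presence_counts(path: str | Path) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", dtype={"peptide": str, "n_samples": int})
    if frame["peptide"].duplicated().any():
        raise FormatError(f"{path}: duplicate peptides in presence table")
    return dict(zip(frame["peptide"], frame["n_samples"]))


def write_peptide_list(peptides: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in sorted(peptides)))


def read_peptide_list(path: str | Path) -> frozenset[str]:
    return frozenset(line.strip().upper()
                     for line in Path(path).read_text().splitlines()
                     if line.strip())


def write_binder_table(table: pd.DataFrame, path: str | Path) -> None:
    table.sort_values(["peptide", "allele"]).to_csv(path, sep="\t", index=False)


def read_binder_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("peptide", "allele", "binder_class"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = frame[~frame["binder_class"].isin(["strong", "weak", "non"])]
    if not bad.empty:
        raise FormatError(
            f"{path}: unknown binder classes {bad['binder_class'].unique().tolist()}")
    return frame


# ---------------------------------------------------------------------------
# results bundle

def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def write_results_bundle(results: Mapping[str, pd.DataFrame], out_dir: str | Path,
                         config: Optional[Mapping] = None,
                         seed: Optional[int] = None) -> dict:
    """Write one TSV per result family plus a JSON manifest.

    The manifest echoes the config and seed and records per-table row counts
    and content digests.  Identical inputs produce byte-identical output.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {out}: {exc}") from exc
    manifest: dict = {
        "config": dict(config) if config else {},
        "seed": seed,
        "tables": {},
    }
    for name in sorted(results):
        table = results[name]
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="NA")
        manifest["tables"][name] = {
            "rows": int(len(table)),
            "sha256": sha256_file(path),
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
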