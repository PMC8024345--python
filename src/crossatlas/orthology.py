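"""Ortholog-group parsing and one-to-one ortholog extraction.

Ortholog groups come as OrthoMCL-style ``groups.txt`` lines: a group id
(optionally ending in ``:``) followed by whitespace-separated gene ids.  Genes
are assigned to a species by a configurable id prefix.  Only groups with
exactly one gene from each species ("one-to-one orthologs") are treated as
functionally equivalent across species; one-to-many and many-to-many groups
are dropped, because duplicated genes commonly neofunctionalize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io import ValidationError, log_stage
from .preprocess import ClusterProfile

__all__ = [
    "OrthologGroups",
    "ParseError",
    "parse_ortholog_groups",
    "extract_one_to_one",
    "align_profiles",
    "AlignedProfiles",
]


class ParseError(ValidationError):
    """A malformed ortholog-group line."""


@dataclass
class OrthologGroups:
    """group id -> per-species gene sets (species keyed 'a' / 'b')."""

    groups: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    n_unassigned: int = 0  # genes matching neither species prefix
    excluded_genes: set[str] = field(default_factory=set)  # seen in >1 group


def parse_ortholog_groups(
    lines,
    species_a_prefix: str,
    species_b_prefix: str,
) -> OrthologGroups:
    """Parse OrthoMCL-style group lines, assigning genes to species by id prefix.

    A gene listed in more than one group is excluded from *all* groups (with a
    warning) — conservative and deterministic.  Genes matching neither prefix
    are ignored and counted.
    """
    groups: dict[str, dict[str, set[str]]] = {}
    seen_in: dict[str, str] = {}
    duplicated: set[str] = set()
    n_unassigned = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"line {lineno}: expected 'group_id gene...', got {raw!r}")
        group_id = tokens[0].rstrip(":")
        if not group_id:
            raise ParseError(f"line {lineno}: empty group id")
        if group_id in groups:
            raise ParseError(f"line {lineno}: group id {group_id!r} repeated")
        members: dict[str, set[str]] = {"a": set(), "b": set()}
        for gene in tokens[1:]:
            if gene.startswith(species_a_prefix):
                species = "a"
            elif gene.startswith(species_b_prefix):
                species = "b"
            else:
                n_unassigned += 1
                continue
            if gene in seen_in and seen_in[gene] != group_id:
                duplicated.add(gene)
            seen_in[gene] = group_id
            members[species].add(gene)
        groups[group_id] = members
    if duplicated:
        warnings.warn(
            f"{len(duplicated)} gene(s) listed in more than one group excluded everywhere, "
            f"e.g. {sorted(duplicated)[0]!r}",
            stacklevel=2,
        )
        for members in groups.values():
            members["a"] -= duplicated
            members["b"] -= duplicated
    log_stage(
        "parse_ortholog_groups",
        groups=len(groups),
        unassigned_genes=n_unassigned,
        excluded_duplicates=len(duplicated),
    )
    return OrthologGroups(groups=groups, n_unassigned=n_unassigned, excluded_genes=duplicated)


def extract_one_to_one(groups: OrthologGroups) -> pd.DataFrame:
    """Return the one-to-one ortholog map (columns ``gene_a``/``gene_b``, sorted by gene_a).

    Exactly the groups with one gene per species become pairs; one-to-many,
    many-to-many and single-species groups are dropped.  The result is checked
    to be a bijection.
    """
    pairs = [
        (next(iter(m["a"])), next(iter(m["b"])))
        for m in groups.groups.values()
        if len(m["a"]) == 1 and len(m["b"]) == 1
    ]
    pairs.sort()
    df = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
    for col in ("gene_a", "gene_b"):
        if df[col].duplicated().any():
            raise ValidationError(
                f"one-to-one extraction produced a repeated gene in {col}; "
                "input groups violate the one-group-per-gene invariant"
            )
    log_stage("extract_one_to_one", pairs=len(df))
    return df


@dataclass
class AlignedProfiles:
    """Two cluster profiles restricted to ortholog pairs present in both."""

    values_a: pd.DataFrame  # clusters_a x pairs (columns: gene_a ids)
    values_b: pd.DataFrame  # clusters_b x pairs (columns: gene_b ids)
    pairs: pd.DataFrame  # gene_a, gene_b actually used
    report: dict


def align_profiles(
    profile_a: ClusterProfile,
    profile_b: ClusterProfile,
    ortholog_map: pd.DataFrame,
) -> AlignedProfiles:
    """Restrict both profiles to mapped ortholog pairs present in both, same order.

    Pairs whose gene is absent from either profile are dropped and counted.
    The pair order is canonical (sorted by ``gene_a``), so a shuffled input
    map yields identical output.
    """
    if len(ortholog_map) == 0:
        raise ValidationError("empty ortholog map")
    omap = ortholog_map.sort_values("gene_a").reset_index(drop=True)
    in_a = omap["gene_a"].isin(profile_a.values.columns)
    in_b = omap["gene_b"].isin(profile_b.values.columns)
    used = omap[in_a & in_b].reset_index(drop=True)
    if len(used) == 0:
        raise ValidationError("no ortholog pair is present in both profiles")
    report = {
        "n_pairs_in": int(len(omap)),
        "n_missing_a": int((~in_a).sum()),
        "n_missing_b": int((~in_b).sum()),
        "n_aligned": int(len(used)),
    }
    log_stage("align_profiles", **report)
    return AlignedProfiles(
        values_a=profile_a.values[used["gene_a"].tolist()],
        values_b=profile_b.values[used["gene_b"].tolist()],
        pairs=used,
        report=report,
    )
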