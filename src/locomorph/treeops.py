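"""Tree reading, editing, grafting and fossil time-calibration.

Conventions: ages are in Ma before present (0 = extant), branch lengths in
Myr, trees are rooted.  Dated trees carry a ``.age`` attribute on every
node; fossil tips sit at their first appearance datum (FAD).  All functions
return new trees and never mutate their inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import dendropy

AGE_TOL = 1e-9


# ---------------------------------------------------------------------------
# I/O

def _schema_for(path, schema: str | None) -> str:
    if schema is not None:
        return schema
    s = str(path).lower()
    return "nexus" if s.endswith((".nex", ".nexus", ".tre")) else "newick"


def read_tree(path, schema: str | None = None) -> dendropy.Tree:
    """Read a single rooted tree from a newick or nexus file."""
    schema = _schema_for(path, schema)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ValueError(f"cannot parse {path} as {schema}: {exc}") from exc
    tree.is_rooted = True
    return tree


def read_trees(path, schema: str | None = None) -> list[dendropy.Tree]:
    """Read a list of trees (e.g. a posterior sample or tree ensemble)."""
    schema = _schema_for(path, schema)
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema=schema, preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"cannot parse {path} as {schema}: {exc}") from exc
    for t in trees:
        t.is_rooted = True
    return list(trees)


def write_tree(tree: dendropy.Tree, path, schema: str | None = None) -> None:
    schema = _schema_for(path, schema)
    tree.write(path=str(path), schema=schema, unquoted_underscores=True,
               suppress_rooting=(schema == "newick"))


def tree_from_newick(s: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Editing

def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Randomly resolve every polytomy into a binary subtree.

    Each polytomy is resolved uniformly at random over all rooted binary
    topologies of its child subtrees (random sequential addition with a
    uniform choice among the 2j-1 insertion positions), so a star on four
    tips hits each of the 15 rooted shapes with equal frequency.  Inserted
    branches have length 0 (dating happens later).  Same seed, same result.
    """
    rng = np.random.default_rng(seed)
    tree = _clone(tree)
    polytomies = [n for n in tree.preorder_node_iter() if len(n.child_nodes()) > 2]
    for node in polytomies:
        children = node.child_nodes()
        for c in children:
            node.remove_child(c)
        # build a uniform rooted binary topology over the child subtrees
        local_root = dendropy.Node()
        local_root.edge.length = 0.0
        local_root.add_child(children[0])
        local_root.add_child(children[1])
        insertable = [children[0], children[1]]  # nodes whose parent edge can split
        for child in children[2:]:
            pos = int(rng.integers(0, len(insertable) + 1))
            new = dendropy.Node()
            new.edge.length = 0.0
            if pos == len(insertable):  # insert above the local root
                new.add_child(local_root)
                new.add_child(child)
                insertable.append(local_root)
                local_root = new
            else:
                target = insertable[pos]
                parent = target.parent_node
                parent.remove_child(target)
                new.add_child(target)
                new.add_child(child)
                parent.add_child(new)
                insertable.append(new)
            insertable.append(child)
        for c in list(local_root.child_nodes()):
            local_root.remove_child(c)
            node.add_child(c)
    return tree


def prune(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Induced subtree on ``keep``; unifurcations suppressed with branch
    lengths summed, so patristic distances among kept tips are unchanged."""
    keep = list(keep)
    present = set(tip_labels(tree))
    missing = [t for t in keep if t not in present]
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    out = _clone(tree)
    out.retain_taxa_with_labels(keep)
    return out


def graft(
    backbone: dendropy.Tree,
    subtree: dendropy.Tree,
    attach_at: str,
    stem_length: float | None = None,
    attach_tip_age: float = 0.0,
    subtree_root_age: float | None = None,
) -> dendropy.Tree:
    """Replace tip ``attach_at`` of the backbone with a dated subtree.

    The classic use is replacing the single extant-beaver tip with a dated
    fossil-castorid supertree.  The stem length defaults to the value that
    preserves the ages on both sides: (age of the attachment node) minus
    (age of the subtree root); a negative value means the subtree root is
    older than its would-be parent, which is an error.  Subtree root age
    defaults to its maximum root-to-tip depth (extant subtree tips).
    """
    out = _clone(backbone)
    tip = next(
        (l for l in out.leaf_node_iter() if l.taxon.label == attach_at), None
    )
    if tip is None:
        raise ValueError(f"attachment tip {attach_at!r} not in backbone")
    sub = _clone(subtree)
    sub_tips = tip_labels(sub)
    if len(sub_tips) == 1:
        tip.taxon = dendropy.Taxon(label=sub_tips[0])
        out.taxon_namespace.add_taxon(tip.taxon)
        if stem_length is not None:
            tip.edge.length = stem_length
        out.update_taxon_namespace()
        return out
    depths = node_depths(sub)
    if subtree_root_age is None:
        subtree_root_age = max(depths[l] for l in sub.leaf_node_iter())
    if tip.edge.length is None:
        raise ValueError("backbone has no branch length at the attachment tip")
    parent_age = attach_tip_age + tip.edge.length
    if stem_length is None:
        stem_length = parent_age - subtree_root_age
    if stem_length < -AGE_TOL:
        raise ValueError(
            "grafting would make a child older than its parent: "
            f"attachment node age {parent_age:g} Ma < subtree root age "
            f"{subtree_root_age:g} Ma"
        )
    sub.migrate_taxon_namespace(out.taxon_namespace)
    parent = tip.parent_node
    if parent is None:
        raise ValueError("cannot graft onto the root tip of a one-tip backbone")
    parent.remove_child(tip)
    sub_root = sub.seed_node
    sub_root.edge.length = max(stem_length, 0.0)
    parent.add_child(sub_root)
    out.update_taxon_namespace()
    return out


# ---------------------------------------------------------------------------
# Dating

def root_length_from_fads(outgroup_fad: float, oldest_ingroup_fad: float) -> float:
    """Root-stem duration as the gap between the oldest ingroup FAD and the
    FAD of the next-oldest relevant outgroup taxon (both in Ma)."""
    rl = outgroup_fad - oldest_ingroup_fad
    if rl <= 0:
        raise ValueError(
            f"outgroup FAD ({outgroup_fad} Ma) must predate the oldest "
            f"ingroup FAD ({oldest_ingroup_fad} Ma)"
        )
    return rl


def load_occurrences(path) -> pd.DataFrame:
    """Occurrence CSV with columns taxon, FAD, LAD (Ma); FAD >= LAD >= 0."""
    occ = pd.read_csv(path)
    return validate_occurrences(occ)


def validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    for col in ("taxon", "FAD", "LAD"):
        if col not in occ.columns:
            raise ValueError(f"occurrence table lacks column {col!r}")
    bad = occ[(occ.FAD < occ.LAD) | (occ.LAD < 0)]
    if len(bad):
        raise ValueError(f"FAD >= LAD >= 0 violated for {list(bad.taxon)}")
    if occ.taxon.duplicated().any():
        raise ValueError("duplicate taxa in occurrence table")
    return occ


def date_equal(
    tree: dendropy.Tree,
    occurrences: pd.DataFrame,
    root_length: float,
    tip_age: str = "fad",
) -> dendropy.Tree:
    """Time-scale a cladogram from tip occurrence dates, "equal" style.

    Tips are dated at their FAD (or the FAD/LAD midpoint with
    ``tip_age="midpoint"``); each internal node starts at the oldest FAD
    among its descendants; the root is pushed back by ``root_length``; and
    every chain of zero-length branches then shares the time of the nearest
    ancestral branch with positive slack equally (node ages evenly re-spaced
    between that ancestor and the bottom of the chain).  The tree span
    (root age minus youngest tip age) is fixed by construction.
    """
    if root_length <= 0:
        raise ValueError("root_length must be > 0")
    occurrences = validate_occurrences(occurrences)
    if tip_age == "fad":
        ages = dict(zip(occurrences.taxon, occurrences.FAD))
    elif tip_age == "midpoint":
        ages = dict(
            zip(occurrences.taxon, (occurrences.FAD + occurrences.LAD) / 2.0)
        )
    else:
        raise ValueError(f"unknown tip_age rule {tip_age!r}")
    out = _clone(tree)
    missing = [t for t in tip_labels(out) if t not in ages]
    if missing:
        raise ValueError(f"tips without occurrence data: {missing}")
    for node in out.postorder_node_iter():
        if node.is_leaf():
            node.age = float(ages[node.taxon.label])
        else:
            node.age = max(c.age for c in node.child_nodes())
    out.seed_node.age += root_length

    for node in out.preorder_node_iter():
        parent = node.parent_node
        if parent is None or parent.age - node.age > AGE_TOL:
            continue
        # walk up to the nearest strictly older ancestor
        path = [node]
        anc = parent
        while anc is not None and anc.age - node.age <= AGE_TOL:
            path.append(anc)
            anc = anc.parent_node
        if anc is None:
            raise ValueError(
                "irreducible zero-length chain at the root; "
                "increase root_length"
            )
        # evenly re-space the intermediate nodes (path[1:] are ancestors)
        chain = path[1:]
        span = anc.age - node.age
        step = span / (len(chain) + 1)
        for i, n in enumerate(chain):
            n.age = node.age + step * (len(chain) - i)

    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    out.seed_node.edge.length = root_length
    assert_dated(out)
    return out


def assert_dated(tree: dendropy.Tree) -> None:
    """Check age monotonicity and non-negative branch lengths everywhere."""
    for node in tree.preorder_node_iter():
        p = node.parent_node
        if p is None:
            continue
        if not hasattr(node, "age") or not hasattr(p, "age"):
            raise ValueError("tree is not dated (missing node ages)")
        if p.age - node.age < -AGE_TOL:
            raise ValueError(
                f"age monotonicity violated: parent {p.age} < child {node.age}"
            )
        if node.edge.length is not None and node.edge.length < -AGE_TOL:
            raise ValueError(f"negative branch length {node.edge.length}")


def ages_table(tree: dendropy.Tree) -> pd.Series:
    """Tip ages (Ma) of a dated tree."""
    return pd.Series(
        {l.taxon.label: l.age for l in tree.leaf_node_iter()}, name="age"
    )


# ---------------------------------------------------------------------------
# Ensembles

def sample_tree_ensemble(
    source_trees: list[dendropy.Tree], k: int, seed: int
) -> list[dendropy.Tree]:
    """Sample ``k`` trees without replacement and randomly resolve each."""
    if k > len(source_trees):
        raise ValueError(f"k={k} exceeds available trees ({len(source_trees)})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(source_trees), size=k, replace=False)
    return [
        resolve_polytomies(source_trees[i], seed=int(rng.integers(2**31)))
        for i in idx
    ]


# ---------------------------------------------------------------------------
# Phylogenetic covariance structure

def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Root-to-node path lengths (Myr); missing edge lengths count as 0."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        p = node.parent_node
        if p is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[p] + (node.edge.length or 0.0)
    return depths


def vcv_matrix(tree: dendropy.Tree, labels: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion covariance structure of the tips.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths.
    """
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    names = [l.taxon.label for l in leaves]
    index = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            C[i, i] = depths[node]
            below[node] = [i]
        else:
            kids = [below[c] for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
            below[node] = [i for ks in kids for i in ks]
    df = pd.DataFrame(C, index=names, columns=names)
    if labels is not None:
        missing = [l for l in labels if l not in df.index]
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        df = df.loc[labels, labels]
    return df
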