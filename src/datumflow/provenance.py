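"""Lineage: where did a commit's data come from?

Every job-origin commit records, at creation time, the exact input commits
and the pipeline spec version that produced it.  Walking those records
transitively yields an acyclic lineage graph whose leaves are user commits:
the complete recipe for reproducing the commit — materialize the leaf data,
re-run the referenced spec versions in order, and the same tree hashes fall
out.
"""

from __future__ import annotations

import json

import networkx as nx

from .catalog import CommitRecord
from .workspace import Workspace


def lineage(ws: Workspace, commit_id: str) -> nx.DiGraph:
    """Build the lineage graph of a commit.

    Nodes are commit ids (``kind='commit'``, with ``repo`` and ``origin``
    attributes) and spec versions (``kind='spec'``, with the pipeline name).
    Edges point from an output commit to each of its input commits and to
    the spec version that transformed them.  User commits are sinks.
    """
    graph = nx.DiGraph()
    seen: set[str] = set()
    frontier = [commit_id]
    while frontier:
        cid = frontier.pop()
        if cid in seen:
            continue
        seen.add(cid)
        commit: CommitRecord = ws.get_commit(cid)
        graph.add_node(
            cid,
            kind="commit",
            repo=commit.repo,
            origin=commit.origin,
            tree_hash=commit.tree_hash(),
        )
        if commit.origin == "job":
            spec_node = f"spec:{commit.spec_version}"
            pipeline = commit.repo  # output repo name == pipeline name
            graph.add_node(spec_node, kind="spec", pipeline=pipeline, version=commit.spec_version)
            graph.add_edge(cid, spec_node)
            for _repo, input_cid in commit.provenance_inputs:
                graph.add_edge(cid, input_cid)
                frontier.append(input_cid)
    return graph


def explain(ws: Workspace, commit_id: str) -> str:
    """Human-readable account of a commit's lineage, sources first."""
    graph = lineage(ws, commit_id)
    lines = []
    # reverse topological order: leaves (user data, specs) before derived commits
    for node in reversed(list(nx.topological_sort(graph))):
        data = graph.nodes[node]
        if data["kind"] == "spec":
            lines.append(f"spec    {data['pipeline']} version {data['version'][:12]}")
        elif data["origin"] == "user":
            lines.append(f"commit  {node} (user data, repo {data['repo']})")
        else:
            inputs = sorted(
                n for n in graph.successors(node) if graph.nodes[n]["kind"] == "commit"
            )
            lines.append(
                f"commit  {node} (output of pipeline {data['repo']},"
                f" from {', '.join(inputs)})"
            )
    return "\n".join(lines)


def lineage_json(ws: Workspace, commit_id: str) -> str:
    graph = lineage(ws, commit_id)
    doc = {
        "nodes": [dict(id=n, **graph.nodes[n]) for n in sorted(graph.nodes)],
        "edges": sorted([u, v] for u, v in graph.edges),
    }
    return json.dumps(doc, indent=2, sort_keys=True)
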