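# hetpaths

Meta-path based similarity search in heterogeneous knowledge graphs.

Biomedical knowledge graphs (KGs) connect entities of many semantic types —
drugs, diseases, proteins, protein functions, side effects. Similarity
search on such graphs must respect those types: a drug–disease–protein path
carries a different meaning than a drug–side-effect–protein path of the
same length. A **meta-path** is an ordered sequence of node types
(e.g. *drug → disease → protein → function*) that defines which walks
between two nodes are admissible; the number and structure of the
conforming path instances quantify how related the two nodes are.

`hetpaths` is a library and command-line tool for:

- representing a node-typed undirected KG loaded from plain edge lists
  (with a node-type table or a combined typed-edge file, including
  OGB-biokg-style entity triples reduced to node-typed form),
- enumerating and counting all path instances conforming to a meta-path
  between node pairs, via typed neighbor queries answered from the edge
  list or a precomputed adjacency index,
- scoring node-pair similarity with **Path Count (PC)**, **Normalized Path
  Count (NPC)**, **Degree-Weighted Path Count (DWPC)** and **PathSim**, or
  user-registered custom metrics,
- aggregating pairwise scores into set-level similarity (mean / median /
  max / min over the full cross-product),
- generating seeded synthetic KGs with a biomedical-style schema for
  testing and scaling studies.

## Metrics

For a meta-path *M* between origin *u* and destination *v*, with PC(u,v|M)
the number of conforming path instances:

| metric | formula | range |
|---|---|---|
| PC | PC(u,v\|M) | ℕ |
| NPC | 2·PC(u,v\|M) / (PC(u,\*\|M) + PC(\*,v\|M)) | [0,1] |
| DWPC | Σ₍paths p₎ Π₍edges (nᵢ,nᵢ₊₁) of p₎ [d_{Tᵢ₊₁}(nᵢ)·d_{Tᵢ}(nᵢ₊₁)]^(−w) | [0, PC] |
| PathSim | 2·PC(u,v\|M) / (PC(u,u\|M) + PC(v,v\|M)), M palindromic | [0,1] |

where d_T(n) is the **typed degree** of n toward type T and w ∈ [0,1]
(default 0.4) damps paths through high-degree hubs. PC, NPC and DWPC use
repeat-free path semantics; PathSim uses walk semantics (see
`docs/methods.md` for why). NPC/DWPC follow Himmelstein & Baranzini (2015),
PathSim follows Sun et al. (2011).

## Worked example

```python
from hetpaths import (fixture_fix1, precompute_adjacency, MetricContext,
                      path_count, normalized_path_count, dwpc, pathsim,
                      RDPF, RDR)

ctx = MetricContext(precompute_adjacency(fixture_fix1()))
print(path_count(ctx, "r1", "f1", RDPF).score)             # 2.0
print(normalized_path_count(ctx, "r1", "f1", RDPF).score)  # 0.6666666666666666
print(dwpc(ctx, "r1", "f1", RDPF, w=0.4).score)            # 0.870550563296124
print(pathsim(ctx, "r1", "r2", RDR).score)                 # 1.0
```

The fixture graph has two drugs sharing a disease whose two associated
proteins both map to one function. Drug `r1` reaches function `f1` by 2
drug–disease–protein–function paths (PC = 2). NPC = 2·2/(2+4) = 2/3
because `r1` sends 2 such paths while `f1` receives 4 (two per drug).
Both paths run through degree-2 hubs, so each contributes a path-degree
product of 8^(−0.4), giving DWPC ≈ 0.871. The two drugs are perfect
drug–disease–drug peers (PathSim = 1): every disease neighbor of either
is shared.

The same queries from the shell:

```bash
hetpaths generate --seed 3 --out-edges e.tsv --out-types t.tsv
hetpaths similarity --edges e.tsv --types t.tsv --header \
    --origin drug0 --destination function1 \
    --metapath drug,disease,protein,function \
    --metric pc --metric npc --metric dwpc
```

```
origin	destination	metapath	metric	score	path_count	truncated
drug0	function1	drug,disease,protein,function	pc	1	1	False
drug0	function1	drug,disease,protein,function	npc	0.0277778	1	False
drug0	function1	drug,disease,protein,function	dwpc	0.0545324	1	False
```

Other subcommands: `paths` (enumerate instances), `set-similarity`
(set-level aggregation with an optional full pair matrix), `index`
(precompute and cache the adjacency index with a content fingerprint).

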