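# dbgmap

Map short reads onto the branching paths of a compacted de Bruijn graph
(CDBG).

`dbgmap` builds a CDBG from a read set (exact k-mer counting, abundance
filtering at a threshold `c`, compaction of maximal non-branching paths into
unitigs), indexes the unitig-boundary (k−1)-mers ("overlaps") as seeds, and
rewrites each query read as a walk of unitigs using a greedy seed-and-extend
algorithm under a cumulative Hamming-mismatch budget. Reads that lie
entirely inside a single unitig are placed by a separate containment stage.
An exhaustive mode replaces the greedy extension with a budget-pruned
depth-first search and returns the minimum-mismatch walk. A simulation
harness generates random genomes and error-bearing reads with recorded error
positions, and scores mappings by recall and "distance to optimum" (the
number of read/path mismatches at error-free positions).

## CLI

```sh
# build a CDBG (writes PREFIX.unitigs.fa, PREFIX.gfa, PREFIX.json)
dbgmap build -k 21 -c 2 --out-prefix graph reads.fastq

# map reads (t mismatches, n anchor failures per direction; defaults 2 and 2)
dbgmap map --graph graph -m 2 -n 2 --out mappings.tsv queries.fastq

# simulate reads from a random genome (FASTQ + origins/error-position sidecar)
dbgmap --seed 7 simulate --length 50000 --n 10000 --read-len 100 \
    --error-rate 0.01 --out-prefix sim

# score a mapping run against the simulation ground truth
dbgmap eval --graph graph --mappings mappings.tsv \
    --origins sim.origins.tsv --out eval.tsv
```

The mapping TSV has one row per read with columns `read_id`, `status`,
`orientation`, `path` (comma-joined unitig ids), `start_offset` (0-based on
the first unitig) and `mismatches`; coordinates are 0-based, half-open.
Graph outputs are unitig FASTA and GFA1 (`S`/`L` lines, `(k-1)M` overlap
CIGAR, `km:i:<k>` header tag).

## Library

```python
from dbgmap import (build_from_reads, build_overlap_index, MappingParams,
                    map_reads, random_genome, simulate_reads, evaluate)

graph = build_from_reads(["TAAGC", "CAAGC"], k=3, c=1)
index = build_overlap_index(graph)
mappings, summary = map_reads(["TAAGC"], graph, index,
                              MappingParams(try_reverse_complement=False))
```

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes, from scratch: `t1`, the maximum number of
unitigs sharing one overlap across 1000 random CDBGs (structural bound 8:
at most four unitigs start and four end with any (k−1)-mer), and `t2`, the
maximum number of candidate unitigs aligned in a single greedy extension
step over 10,000 simulated reads (structural bound 4, one per extending
base).
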