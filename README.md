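# sterncode

Construction of DNA data-storage coding sets with a Levy-flight sooty tern
optimizer.

## The problem

Random access in a DNA storage pool works by PCR-amplifying the fragments
whose *address* sequence matches a primer.  Addresses are short, fixed-length
DNA codewords, and the pool is only reliable if the address set satisfies
combinatorial constraints:

* **GC content** — each codeword keeps its G+C fraction inside a window
  (40–60% by default), for stable and uniform melting behaviour;
* **no runlength** — no two adjacent bases are equal, because homopolymer
  runs are misread during synthesis and (nanopore) sequencing;
* **minimum edit distance** — every pair of codewords has Levenshtein
  distance at least *d*, so that insertion/deletion/substitution errors
  cannot convert one address into another.

A set of mutually compatible codewords is a *coding set*
`A_GC,NL(n, d)`; the larger the set, the more files can be addressed at a
given codeword length.  Its information density is the code rate
`R = log4(M) / n` for a size-`M`, length-`n` set.  Finding maximum sets is a
hard combinatorial problem (a maximum clique in the compatibility graph), so
published tables are heuristic lower bounds.

## The method

The search engine is the Sooty Tern Optimization Algorithm (STOA), a swarm
metaheuristic whose agents carry positions in a box.  Each iteration has a
*migration* move

```
C = SA · P,   M = CB · (P_best − P),   D = C + M,
SA = Cf − z·Cf/max_iter,   CB = 0.5 · Rand
```

and a *spiral attack* onto the best position: with angle `i ~ U[0, 2π]` and
contracting radius `R = u·e^{−iv}`, the offsets `x' = R sin i`,
`y' = R cos i`, `z' = R·i` give the update `P ← (D · (x'+y'+z')) · P_best`
(elementwise).  The Levy variant (LSTOA) perturbs late-phase updates with
heavy-tailed Mantegna steps, `P(l) ~ l^{−(1+β)}`, `0 < β ≤ 2`, letting the
swarm escape local optima.

Coding sets are grown incrementally: each growth step searches `[0, 4]^n`
with the LSTOA, decodes positions into codewords (coordinate `c` → base
`floor(c)`), scores candidates against the current members, and admits a
candidate only if it is individually valid, distinct, and at edit distance
≥ `d` from every member.  The best set over several seeded restarts is kept
and re-checked by an independent validator.  An exact maximum-clique oracle
(`n ≤ 6`) provides ground truth at tiny sizes, and thirteen classic
benchmark functions (sphere, Rosenbrock, Ackley, Rastrigin, ...) exercise
the optimizer itself.

## Worked example

```
$ sterncode build -n 6 -d 3 --seed 1 --out demo_set.txt
size 34 rate 0.4240

$ head -4 demo_set.txt
# coding set, 34 codewords
TCTCTC
ATCTGC
AGCTCT

$ sterncode validate demo_set.txt -n 6 -d 3
coding set: 34 codewords, profile n=6 d=3 GC=[0.40,0.60] NRL=on UA=off
verdict: VALID

$ sterncode oracle -n 4 -d 3
maximum size 6
```

The build found 34 homopolymer-free codewords of length 6, GC-balanced,
pairwise edit distance ≥ 3 — above the published lower bound of 30 for this
profile — at code rate `log4(34)/6 ≈ 0.424` information symbols per
nucleotide.  The `validate` command re-checks the file with the independent
validator, and `oracle` solves tiny profiles exactly (6 is provably maximum
for `n=4, d=3`).

The library mirrors the CLI: `build_code_set`, `validate_code_set`,
`exact_max_code_set`, `lstoa_optimize`, `run_suite`, and `code_rate` are the
main entry points (see `docs/methods.md` for the model details and design
choices).

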