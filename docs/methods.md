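# Methods

Models, parameter choices, and numerical conventions. Problem sizes quoted
here (planted family sizes, rep counts) are this package's own test sizing
choices for desk-scale runs.

## Domain rule engine (`ringzf.domains`)

A RING subtype is a `LigandRule`: an ordered list of 8 ligand slots (9 for
the accessory IBR rule), each with a set of allowed residues and, for all
but the last slot, an inclusive spacer range to the next slot. The default
table:

- **RING-M** (priority 0): `M-X2-R-X14-C-X1-H-X2-C-X2-C-X10-C-X2-C` —
  fixed spacers, Met/Arg at ligand positions 1–2.
- **RING-D** (priority 1): the generic consensus with Asp required at
  ligand slot 5.
- **RING-H2** (priority 2): generic consensus with His at slots 4 and 5
  (C3H2C3).
- **RING-HC** (priority 3): generic consensus with His at 4, Cys at 5
  (C3HC4).
- **IBR** (accessory): 9-slot C6HC with spacers 4, 14–30, 1–4, 4, 2, 4, 4, 4.

Generic consensus spacers: 2, 9–39, 1–3, 2–3, 2, 4–48, 2.

**Scanning.** For each start position whose residue satisfies slot 1, the
rule is compiled to an anchored regular expression with *lazy* quantifiers
for the variable spacers. Lazy backtracking order equals lexicographic
order on the spacer vector, so the first regex match is exactly the
smallest-spacer assignment — the engine's tie-break rule. Tests verify this
equivalence against an independent recursive enumeration of all valid
ligand assignments.

**Classification.** Core rules are applied in priority order; when two core
rules match at the same first-ligand position only the higher-priority
label survives. Accessory (IBR) hits never suppress core hits. A protein's
subtype is that of its first core domain; multi-domain proteins are counted
once and reported separately. RING-HC splits into HCa/HCb by a configurable
criterion (default: spacer after slot 6 ≥ 8 → HCa).

**Census arithmetic.** Percentages use `decimal.Decimal` with
`ROUND_HALF_UP` at one decimal, so printed values like 59/75 → 78.7 and
112/138 → 81.2 are exact, not float artifacts.

## Physicochemical properties (`ringzf.protparam`)

- MW: sum of average residue masses (Biopython's table) + one water.
- GRAVY: mean Kyte–Doolittle hydropathy.
- Instability index: Guruprasad DIWV dipeptide weights, `10/L · Σ`;
  unstable strictly above 40.
- Aliphatic index: `X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu))` in mol%.
- pI: bisection on the Henderson–Hasselbalch net charge with an
  EMBOSS-style pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1,
  H 6.5, K 10.8, R 12.5, Y 10.1), tolerance 1e-3. Tests compare against a
  vectorized fine-grid scan (step 1e-4) of the same charge model.
- Atomic composition: per-residue C/H/N/O/S formula sums minus (L−1)
  waters.

## Ka/Ks and divergence time (`ringzf.molevol`)

Nei–Gojobori (1986) counting:

- **Sites.** Each codon position contributes synonymous fraction =
  (synonymous single-nucleotide changes)/3; changes creating stop codons
  are never counted synonymous, so S + N = 3 per codon exactly.
- **Differences.** For codons differing at k positions, all k! substitution
  orderings are enumerated; paths passing through a stop codon are
  excluded and the (syn, nonsyn) tallies averaged over the remaining
  paths. A pair whose every path hits a stop contributes nothing and is
  flagged (`dropped`).
- **Distances.** p = d/sites, Jukes–Cantor correction
  `K = −3/4 · ln(1 − 4p/3)`, undefined (saturated) at p ≥ 3/4.
- **Clock.** `T = Ks / (2λ) × 10⁻⁶` Mya with λ = 6.5×10⁻⁹
  substitutions/site/year by default.
- Selection call: ω < 1 purifying, ω > 1 positive (tolerance 1e-9),
  undefined when Ks = 0 or saturated.

Oracle: exhaustive depth-first path enumeration over all sense-codon
pairs (complete 61×61 sweep) plus Biopython's independent NG86 on
stop-safe codons (restricted so stop-handling conventions cannot
confound the comparison).

## Clustering, distances, trees (`ringzf.phylo`)

- **Redundancy removal** (CD-HIT-style surrogate): sequences sorted by
  decreasing length; each joins the first existing representative with
  identity > cutoff (default 0.95), else founds a cluster. Identity =
  matched columns of an edlib global alignment / length of the shorter
  sequence.
- **p-distances**: mismatches / comparable (gap-free in both) columns;
  error if no comparable columns.
- **Neighbor joining** (Saitou–Nei): Q-criterion, ties broken by smallest
  index pair, negative branch lengths clamped to 0 and flagged. On any
  additive matrix NJ returns the unique generating tree; tests verify
  topology against exhaustive enumeration of all unrooted topologies with
  least-squares branch fitting for n ≤ 6, and certify n = 7–8 by requiring
  the NJ tree's patristic distances to equal the input matrix exactly
  (uniqueness of the additive representation).
- **Bootstrap**: columns resampled with replacement; support = % of
  replicate trees containing each bipartition of the full-data tree.

## Promoters (`ringzf.promoters`)

Windows are the 1.5 kb (configurable) upstream of the gene start,
strand-aware (`[start−L, start)` on +, `[end, end+L)` reverse-complemented
on −), clipped at contig edges with a truncation flag. Motifs are IUPAC
patterns scanned on both strands via lookahead regexes so overlapping
occurrences are all reported; a palindromic motif yields one hit per
strand at the same locus; `N` in the sequence matches nothing. The census
reports per-motif gene presence (half-up percentage) and occurrence
counts, plus category totals.

## Expression (`ringzf.expression`)

- Group 1 / Group 2: TPM ≥ 10 / < 1 in ≥ 80% of developmental stages
  (Group 1 wins if both).
- Group 3 / Group 4: (treatment + 0.5)/(control + 0.5) ≥ 2 / ≤ 0.5 in
  ≥ 50% of treatments; genes meeting both are logged and left ungrouped.
- Heat maps: per-row z-scores of log2(TPM+1); constant rows flagged and
  zeroed. Ordering by average-linkage clustering on 1 − Pearson
  correlation (constant rows at distance 1).
- qPCR: ΔΔCt = (CT_target − CT_ref)_cond − (CT_target − CT_ref)_control,
  fold = 2^−ΔΔCt; the control condition maps to fold 1 exactly.

## Synthetic data (`ringzf.synthetic`)

Design goal: with zero noise, every planted answer is recovered *exactly*;
noise knobs then probe robustness.

- Protein backgrounds use the ligand-free alphabet `AGLSTVPEQN` (no
  C/H/D/M/R), so domains exist only where planted. Multi-domain proteins
  separate domains by ≥ 60 filler residues, more than the largest spacer
  (48), so no cross-domain assignment can satisfy any rule. Decoys carry
  at most seven ligand-capable residues spaced ≥ 60 apart.
- Codon pairs differ by exactly the requested number of synonymous and
  nonsynonymous single-nucleotide changes, one per codon, so NG86 counts
  are predictable in closed form.
- Promoters use an {A,T} background: every default motif (and its reverse
  complement) contains C or G, so the background can never spell a motif;
  the generator additionally verifies that all scanner hits fall inside
  planted spans and resamples otherwise. A planted locus may legitimately
  match a second overlapping motif (e.g. ABRE inside G-box).
- TPM matrices plant the four groups at separated levels (high 50,
  low 0.2, basal 5, induced 40) with optional multiplicative lognormal
  noise of a given CV; CT tables realize exact fold changes
  (CT = control − log2(fold)) with optional Gaussian noise.

Limits: generators produce statistically unrealistic but logically exact
data — real proteomes have ligand residues everywhere, real promoters are
GC-mixed. They validate algorithmic correctness, not biological realism.

## Determinism and test sizing

All randomness flows through seeded `numpy.random.default_rng`; identical
seeds give byte-identical outputs. Oracle comparisons use 200 random
sequences for the domain scanner, the full 61×61 codon sweep, 100 random
trees, and 40–200 random promoters — sized to keep the full suite fast
while covering each algorithm's branch structure.
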