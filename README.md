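# adld — dot-plot comparison of protein sequences via PCA residue scores

`adld` measures the similarity of protein sequences with a numeric dot
plot.  Each of the 20 amino acids is reduced to a single real number — its
**total score** — by a principal-component analysis of nine physicochemical
properties (molecular weight, hydropathy index, pK₁, pK₂, isoelectric
point, solubility, codon count, frequency in human proteins, van der Waals
radius).  A protein sequence becomes a real-valued vector, and a pair of
sequences becomes a banded dot plot: coordinate (i, j) is an
*alignment point* (AP) when |tᵢ − tⱼ| ≤ ε and |i − j| ≤ w, with band
half-width

    w = ξ        if N₁ − N₂ ≤ ξ
        N₁ − N₂  otherwise.

Reducing the plot to maximal diagonal runs of at least δ consecutive APs
(*similar fragments*, SFs) plus the leftover main-diagonal points (*free
points*, FPs) gives the **Alignment Diagonal Line Diagram** (ADLD).  Runs
on the main diagonal are aligned identical stretches; runs on a parallel
diagonal at offset o = j − i mark stretches that realign after an
insertion or deletion of |o| residues.  The pair's *similarity degree* is

    SD = Σ fragment lengths + number of free points

and over a collection the distance matrix is sᵢⱼ = 1 − min(1, dᵢⱼ/dᵢᵢ)
with dᵢⱼ = SD of pair (i, j), so 0 means indistinguishable and 1 means no
retained structure.  The matrix feeds standard neighbor joining for tree
building.  Intended users: anyone doing alignment-free similarity analysis
or quick visual comparison of protein families (globins, mitochondrial
ND5, viral spike proteins, ...).

## Worked example

The residue score table (first rows shown):

```bash
$ adld scores
symbol,total_score
A,-0.9324
C,-0.5985
D,-0.6709
...
```

Comparing the 10-residue fragments `MTMHTTMTTL` and `MTMYATMTTL` (they
differ at positions 4 and 5):

```bash
$ printf '>Hu\nMTMHTTMTTL\n>Gor\nMTMYATMTTL\n' > pair.fa
$ adld pair --fasta pair.fa
{
  "pair": ["Gor", "Hu"],
  "lengths": [10, 10],
  "width": 10,
  "fragments": [
    {"track_offset": 0, "start": [1, 1], "end": [3, 3], "length": 3},
    {"track_offset": 0, "start": [6, 6], "end": [10, 10], "length": 5}
  ],
  "free_points": [],
  "total_fragment_length": 8,
  "similarity_degree": 8
}
```

Two main-diagonal fragments (positions 1–3 and 6–10, lengths 3 and 5)
survive the δ = 3 run filter; the two mismatched positions leave no free
points, so SD = 8.  Against the self-score d₁₁ = 10 this gives distance
s = 1 − 8/10 = 0.2.  `adld matrix --fasta set.fa --out sm.csv` builds the
distance matrix for a whole FASTA file, and
`adld tree --matrix sm.csv --out tree.nwk` writes its neighbor-joining
tree as Newick.  `adld synth` generates seeded random sequences with
controlled substitutions/insertions/deletions for testing.

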