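# cleavemap

Cleavage-site mapping for sequence-specific endoribonucleases (MazF-family
toxins) from RNA-seq coverage profiles, plus binomial motif-burden ranking
of coding sequences — the two statistics behind asking *where does the
enzyme cut?* and *which transcripts does it hit hardest?*

Intended for microbiologists and bioinformaticians analysing toxin
endoribonuclease specificity (e.g. the UGG-specific MazF of the
ammonia-oxidising chemolithotroph *Nitrosomonas europaea*) or any
motif-specific RNase read out by 5'-end sequencing.

## The statistics

**Relative coverage increase (RCI).**  A cut deposits a new fragment 5'
end, so coverage jumps at the nucleotide just downstream.  With c(n) the
coverage at position n (pseudo-count 1 substituted for zeros),

    RCI(n+1) = c(n+1) / c(n).

Boundaries with downstream coverage ≥ 100 compete across all references for
the overall top 50 RCI values; their ±5 nt windows are aligned into a
position weight matrix, and a consensus base is called per column when its
frequency is ≥ 0.5 and the column's information content (2 − H bits) is
≥ 1.  Labels run −5..+5 with the coverage-increase nucleotide at 0, so a
UGG cutter that cleaves 5' of the first G calls U,G,G at −1, 0, +1.

**Motif burden.**  For a CDS of length L with per-position motif
probability p = f(T)·f(G)² (its own base composition), expected count
E = p(L−2) and observed overlapping count K, the burden statistic is the
binomial upper tail

    P = Pr(X ≥ K),  X ~ Binomial(L − 2, p),

and transcripts are ranked by ascending P.

A seeded synthetic-data generator (Poisson 5'-end counts convolved with a
read-length box) stands in for the digestion experiment, with ground-truth
cut sites for end-to-end validation.

## Worked example

The numbered drivers under `analysis/` run the whole study desk-scale:

```sh
python analysis/01_simulate_digestion.py
python analysis/02_map_cleavage_sites.py
```

prints (seed 7):

```
top-50 boundaries selected; 50/50 on true sites
consensus: NNNNUGGNNNN (called span (-1, 1), cut 5' of label 0)
information content at core labels: -1: 2.00 bits, 0: 2.00 bits, 1: 2.00 bits
```

— every selected boundary is a true cleavage site, and the called motif is
UGG spanning labels −1..+1 at full 2-bit conservation, i.e. the enzyme cuts
immediately 5' of the first G.

```sh
python analysis/03_burden_replay.py
```

recomputes P for 17 published *N. europaea* gene parameter sets
(hydroxylamine oxidoreductase *hao*, RubisCO large subunit *rbcL*, the
ammonia monooxygenase *amo* subunits, and the other top-ranked CDS) from
their (L, E, K) values, e.g.

```
hao2                               1713   52    3.547E-07     3.56E-07   0.0037
rbcL                               1422   53    7.184E-07     7.15E-07   0.0048
```

— the recomputed tails match the published values to ~3 significant
figures (worst relative error 0.6%, attributable to the two-decimal
rounding of published E).  `python analysis/04_enrichment_recovery.py`
shows the ranking recovers 22/25 of a planted 2×-enriched CDS subset in the
top 5%.

The same steps are available as a CLI:

```sh
cleavemap pipeline --seed 7 --out-dir run/        # simulate -> detect -> logo
cleavemap burden --cds cds.fa --motif TGG --out burden.tsv
cleavemap burden --params analysis/data/ne_burden_params.tsv --out replay.tsv
```

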