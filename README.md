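# clipsplice

Integrative post-transcriptional analysis for an RNA-binding,
chromatin-associated protein: detect alternative-splicing (AS) events from
RNA-seq splice-junction and coverage summaries, score their differential
usage between a knockout and a control condition, stratify target genes by
CLIP-seq (mRNA) and ChIP-seq (promoter) binding affinity, test whether the
knockout response tracks binding strength, and quantify splicing-motif
enrichment and exon–intron boundary read-density profiles. A
planted-ground-truth transcriptome simulator generates the full study
design at desk scale, so every stage is testable against known answers.

Intended for computational biologists who have junction counts, per-base
coverage, peak calls with fold enrichments, and gene counts — not raw
reads — and want a reproducible, scriptable pipeline over those summaries.

## The statistics at the core

**Differential splicing.** Each AS event has a *model* form (the annotated
isoform's junctions) and an *alternative* form (the conflicting junctions;
for intron retention, intron-body reads). With pooled per-condition read
counts $(a_1, m_1)$ and $(a_2, m_2)$ for alternative and model reads, the
event's p-value is a two-sided Fisher's exact test on the 2×2 table
$[[a_1, m_1], [a_2, m_2]]$, and its effect size is the **RASE ratio**

$$\mathrm{RASE} = \left| \frac{a_1}{a_1+m_1} - \frac{a_2}{a_2+m_2} \right|,$$

a ΔPSI-like quantity on $[0,1]$. An event is a *regulated* AS event (RASE)
when $p < 0.05$ and RASE ratio $> 0.2$ (a Benjamini–Hochberg FDR mode is
also provided). Eight event types are classified from junction topology:
CassetteExon, ES, MXE, A5SS, A3SS, 5pMXE, 3pMXE, and IntronR.

**Intron retention.** An intron is called retained when boundary evidence
exists at either splice site and its mean depth is ≥ 20% of the flanking
exon depth and ≥ 2× the gene's background intronic depth. The ratio of
mean intron depth to mean flanking-exon depth is the **IR intensity**.

**Binding affinity.** Per gene, CLIP affinity = peak-derived binding
signal / control FPKM; ChIP promoter affinity = Σ fold enrichment of peaks
in the window TSS −10 kb … +3 kb (strand-aware). Bound genes are split into
strong/median/weak tertiles, and per-tier distributions of knockout/control
log2 fold changes (abundance, or AS-ratio) are compared with one-way ANOVA
plus Tukey's pairwise test, with ECDF curves and a strong-vs-weak
Kolmogorov–Smirnov statistic. Gene-set overlaps use an exact upper-tail
hypergeometric test; co-expression screening uses |Pearson r| ≥ 0.3.

**Motifs and metagenes.** fuzznuc-style patterns (5'ss consensus AGGUAAG
and its degenerate form `[GA]GT[AG]AG`, 3'ss
`T[TCG][TCG]N[TC]TN[TC]AG`, the GAAGAA exonic splicing enhancer, the UGGAC
m6A context, and a U-rich window rule) are scanned with overlapping
matches; peak-level frequencies are tabulated per genomic region, and
per-gene motif counts are related to binding signal in 11 bins (0–9 and
≥10). Metagene profiles accumulate depth over 100 nt of internal exon and
400 nt of adjacent intron at both splice sites, divide by gene numbers per
group, and normalize all groups by the single global maximum.

## Worked example

```python
from clipsplice.simulate import SimConfig, simulate_all
from clipsplice.splicing import (detect_junction_events, differential_splicing,
                                 call_intron_retention)
from clipsplice.io import pool_tracks

data = simulate_all(SimConfig(seed=42, n_genes=60))
det = detect_junction_events(data.models, data.junctions)
cov = {c: pool_tracks([data.coverage[s] for s in names])
       for c, names in data.samples.items()}
ir, seen = [], set()
for c in sorted(cov):
    for ev in call_intron_retention(data.models, cov[c]):
        if ev.event_id not in seen:
            seen.add(ev.event_id); ir.append(ev)
rase = differential_splicing(det.events + ir, data.junctions, data.samples,
                             coverage=cov)
sig = rase[rase.significant]
print(f"{len(det.events)} junction events + {len(ir)} retained introns; "
      f"{len(sig)} significant in {sig.gene_id.nunique()} genes")
print(sig[["event_id", "type", "p_value", "rase_ratio"]].head(5).to_string(index=False))
```

prints

```
21 junction events + 3 retained introns; 24 significant in 24 genes
                         event_id         type      p_value  rase_ratio
gene0004:CassetteExon:12428-15466 CassetteExon 4.588567e-54    0.406743
          gene0005:ES:14607-16730           ES 8.196459e-32    0.404502
         gene0007:MXE:19415-22241          MXE 2.872455e-91    0.403988
        gene0010:A5SS:29633-30243         A5SS 5.815674e-54    0.411285
        gene0011:A3SS:33925-35078         A3SS 3.416604e-33    0.363073
```

The simulator planted AS switches with ΔPSI = 0.4 in 40% of the 60 genes;
all of them come back with the correct type, a tiny Fisher p, and a RASE
ratio close to the planted inclusion change (the CassetteExon value of 0.30
reflects that skip-junction proportions compress multi-junction inclusion
paths). The same objects feed the affinity, motif, and metagene stages; or
run everything at once:

```bash
clipsplice run --out my_run --seed 42     # full bundle of TSV tables
clipsplice simulate --out my_sim --seed 1 # just the synthetic dataset
```

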