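# tfbscreen

Mining transcription-factor-based biosensors (TFBs) from bacterial
genomes, plus Hill dose–response characterization of the sensors found.

A TFB is a transcriptional regulator and its cognate promoter whose
output responds to a small-molecule ligand — the workhorse of
high-throughput strain screening and metabolite detection. Known
biosensors cover only a sliver of chemical space; for a new target
metabolite one usually has no regulator to start from. `tfbscreen`
exploits a recurring genomic architecture: the genes that catabolize a
metabolite tend to cluster in an operon, and the regulator that senses
the metabolite is often encoded immediately upstream, transcribed
divergently from a shared intergenic region.

The workflow, given a target compound and a maximum catabolic chain
length:

1. **Chain enumeration** — from a KEGG-style knowledge base (compound →
   reactions, reaction → equation + EC numbers), depth-first expand all
   enzymatic chains that sequentially degrade the target, honoring the
   written reaction direction. Each chain is a unique ordered EC
   sequence of length 2..`max_len`.
2. **Genome screening** — find organisms whose enzyme annotations cover
   every chain step, map the genes onto NCBI-style feature tables, and
   keep arrangements where the chain genes share a replicon and strand
   with at most `gap_tolerance` (default 2) genes between neighbors.
3. **Regulator scoring** — walk upstream of the operon's 5′ gene for the
   nearest opposite-strand gene annotated with a regulatory keyword
   ("regulator", "activator", "repressor"). Score the pair 0 when
   adjacent, deducting 1 per intervening gene on the operon's strand and
   2 per intervening gene on the regulator's strand, clamped at −500.
   Higher scores mean a more plausible sensor.
4. **Dose–response characterization** — normalize reporter fluorescence
   by blank-corrected OD600 and fit the four-parameter Hill model

   ```
   y(I) = b0 + (bmax − b0) · I^h / (Km^h + I^h)
   ```

   (`b0` basal output, `bmax` maximal output, `Km` half-maximal inducer
   concentration, `h` Hill coefficient). The sensor's *operational
   range* is the inducer interval covering 5–95 % of the response span,
   in closed form `I(f) = Km · (f/(1−f))^(1/h)`.

All inputs can be generated synthetically (`tfbscreen.simulate`):
fixture knowledge bases, genomes with planted operon–regulator
arrangements and a ground-truth score table, and noisy dose–response
assays — so the whole pipeline is testable end to end without network
access.

## Worked example

The β-L-arabinose catabolism graph (four reactions) yields exactly three
chains at maximum length 3:

```python
>>> import tfbscreen as t
>>> kb = t.build_arabinose_fixture()
>>> for c in t.enumerate_chains(kb, "C02479", max_len=3):
...     print(c.length, " -> ".join(c.ec_sequence))
2 5.3.1.4 -> 2.7.1.16
3 5.3.1.4 -> 2.7.1.16 -> 5.1.3.4
3 5.3.1.4 -> 2.7.1.16 -> 5.1.3.22
```

All three start with L-arabinose isomerase (EC 5.3.1.4) and ribulokinase
(EC 2.7.1.16); the two length-3 chains append one of the two
L-ribulose-5-phosphate epimerases.

A full mining run against simulated genomes with planted truth:

```sh
tfbscreen mine --compound C02479 --max-length 3 \
    --kb study/kb --genomes study/genomes \
    --org-map study/organism_map.tsv --out study/out
```

prints per-stage counts (`chains enumerated: 3`, `candidates total: 5`)
and writes one ranked CSV per chain, e.g.
`C02479_len2_5.3.1.4_2.7.1.16.csv`:

```
organism_code,assembly_accession,replicon,enzyme_locus_tags,regulator_locus_tag,regulator_annotation,score
org1,GCA_900000101.1,ORG1_CHR01,ORG1_00025;ORG1_00026,ORG1_00024,LysR family transcriptional regulator,0
org2,GCA_900000102.1,ORG2_CHR01,ORG2_00040;ORG2_00041,ORG2_00037,LysR family transcriptional regulator,-2
org3,GCA_900000103.1,ORG3_CHR01,ORG3_00031;ORG3_00032,ORG3_00035,LysR family transcriptional regulator,-3
```

Score 0 is the ideal divergent-adjacent architecture; −2 means the
regulator sits two operon-strand genes away, and so on.

Sensor characterization from fitted Hill parameters:

```sh
$ tfbscreen hill range --h 2.13 --km 167
{"km_uM": 167.0, "hill_coefficient": 2.13, "lower_uM": 41.91434346570068,
 "upper_uM": 665.3808146326351, "lower_uM_rounded": 42, "upper_uM_rounded": 665}
```

i.e. an S-mandelate sensor with `h = 2.13`, `Km = 167 µM` responds
usefully between about 42 and 665 µM. `tfbscreen hill fit --input
points.csv --out fit.json` fits the parameters from raw
fluorescence/OD readings; the sklearn-style `HillRegressor` exposes the
same fit with `fit`/`predict`/`get_params` for pipeline composition.

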