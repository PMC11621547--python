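# rnagen

Generative sequence and structure models for RNA families, with the
quality-control filters and mutation-discovery statistics needed to go
from an alignment of a family to a ranked list of candidate
function-altering point mutations.

## The problem

Structured RNAs such as the large-subunit ribosomal RNA tolerate only a
narrow set of substitutions, and the substitutions that change a
phenotype — for example, thermostability — are hard to spot by eye in an
alignment. One productive strategy is to train a generative model on all
known members of a family (the **pretrained**, PT, model), finetune a
copy on a phenotypically defined subpopulation such as sequences from
hyperthermophiles (optimal growth temperature ≥ 60 °C; the **finetuned**,
FT, model), and then ask where the two models disagree:

* **Per-column Jensen–Shannon divergence.** Generate a set of sequences
  from each model (temperature-scaled sampling seeded with the 5' end of
  a reference sequence), compare per-column nucleotide frequency
  distributions with JSD (base 2, so JSD ∈ [0,1]), mask the seed columns
  and columns under 50% occupancy, and rank the rest. High-JSD columns
  are where finetuning changed the model's preferences.
* **ΔΔlogP likelihood scoring.** Graft a candidate substitution into the
  wild-type sequence and compute
  `ΔΔlogP = (log P_FT(mut) − log P_PT(mut)) − (log P_FT(wt) − log P_PT(wt))`.
  Positive values mean the FT model supports the mutant better than the
  PT model, relative to wild type. Candidates are placed on a percentile
  scale against the ΔΔlogP distribution of all 3L single mutants.

Two model families are implemented from scratch (NumPy, with an
in-package autodiff engine):

* an **RNA language model** — a compact decoder-only causal transformer
  over overlapping n-gram tokens (n ∈ {1,2,3}, step 1, so per-token
  perplexity is per-nucleotide perplexity; 4 is the random floor, 1 is
  perfect certainty), with rotary position encoding in every attention
  layer, RMS normalization, and padding excluded from all losses;
* a **structure-conditioned model** — an encoder/decoder over a
  k-nearest-neighbor contact graph built from minimum inter-nucleotide
  atomic distances, with Gaussian-RBF distance edge features and causal
  sequence decoding over alignment columns.

Around them: FASTA/Stockholm I/O with WUSS consensus-structure parsing,
reference-coordinate projection, the four-filter sequence QC battery
(ambiguity, consensus coverage, length z-score, disrupted canonical
base-pair z-score), greedy identity clustering for train/test splits,
contact-map construction and comparison (`Corr(A,B) = ΣAB/√(ΣA²ΣB²)`),
and a synthetic-family generator with planted thermophile signal that
serves as ground truth for the whole pipeline.

## Worked example

Simulate a 200-column family (1,200 rows, 20% thermophiles, five planted
U→C shifts at δ = 0.9), pretrain on everything, finetune on the
thermophiles, generate 300 sequences from each model, and scan:

```python
from rnagen.synthetic import SyntheticFamilySpec, sample_family
from rnagen.tokenizer import build_vocab, encode
from rnagen.lm import (LMConfig, TrainConfig, RnaLM, train, finetune,
                       GenerationConfig, generate)
from rnagen.mutation_scan import (jsd_scan, top_columns, MutationSpec,
                                  ddlogp_batch, single_mutant_reference)

fam = sample_family(SyntheticFamilySpec.default(n_sequences=1200, delta=0.9,
                                                rng_seed=0))
tok = build_vocab(3)
all_tok = [encode(s, tok).ids for s in fam.family.ungapped()]
th_tok = [encode(s, tok).ids for s in fam.family.ungapped()
          if s.id.startswith("thermo")]

pt = RnaLM(LMConfig(context_window=202, n_layers=2, n_heads=2, d_embed=48),
           tok, rng_seed=0)
pt, rep = train(pt, all_tok[:1100], all_tok[1100:], TrainConfig(
    lr_start=2e-3, lr_end=2e-4, decay_iters=1200, batch_size=16,
    max_iters=1200, eval_interval=200, early_stop_patience=4))
ft, _ = finetune(pt, th_tok[:200], th_tok[200:], TrainConfig(
    lr_start=1e-3, lr_end=1e-4, decay_iters=600, batch_size=16,
    max_iters=600, eval_interval=150, eval_batches=None, rng_seed=1))

gens = {}
for name, model in (("pt", pt), ("ft", ft)):
    res = generate(model, GenerationConfig(seed_prefix=fam.consensus[:25],
                                           temperature=0.5, n_sequences=300,
                                           max_nucleotides=200, rng_seed=7))
    gens[name] = [s.residues[:200].ljust(200, "-") for s in res.sequences]

div = jsd_scan(gens["pt"], gens["ft"], seed_mask_length=27)  # 25 nt + (n-1)
print(sorted(c + 1 for c in top_columns(div, 10)))

wt = fam.consensus
ref = single_mutant_reference(ft, pt, wt)
specs = [MutationSpec([(c + 1, t["from"], t["to"])])
         for c, t in sorted(fam.truth.items())]
for ms, sc in zip(specs, ddlogp_batch(ft, pt, wt, specs)):
    print(f"{ms.name}: ddlogp = {sc.ddlogp:+.2f} "
          f"percentile = {ref.percentile(sc.ddlogp):.1f}")
```

Output (about six minutes on one CPU):

```
pretrained validation perplexity: 1.144
finetuned  validation perplexity: 1.227
top-10 JSD columns (1-based): [41, 56, 71, 72, 84, 97, 98, 111, 131, 168]
planted columns     (1-based): [41, 56, 84, 111, 131]
  U41C: ddlogp = +7.15  percentile = 99.8
  U56C: ddlogp = +5.43  percentile = 99.5
  U84C: ddlogp = +1.81  percentile = 93.0
 U111C: ddlogp = +5.95  percentile = 99.7
 U131C: ddlogp = +4.84  percentile = 99.3
```

All five planted columns appear in the top-10 JSD ranking (the extra
hits are helix columns shifted by the thermophiles' mild GC
enrichment), and every planted substitution scores far above the 75th
percentile of the single-mutant reference — the model pair recovers the
planted thermophile signal both ways. Mutation names use 1-based
reference numbering (`U41C` = U at position 41 replaced by C).

The same pipeline is available from the shell:

```bash
rnagen simulate --n-sequences 1200 --length 200 --seed 0 --out-prefix fam
rnagen tokenize --fasta fam.fa -n 3 --out fam.tok.npz
rnagen train --tokens fam.tok.npz --context-window 202 --max-iters 1200 --out pt.npz
rnagen generate --checkpoint pt.npz --seed-prefix <5'-seed> --out gen.fa
rnagen scan jsd --pt-fasta gen_pt.fa --ft-fasta gen_ft.fa --width 200 \
    --seed-mask-length 27 --out jsd.tsv
```

Every artifact-producing command writes a JSON manifest (config, seeds,
input/output digests) beside its output; replays with the same seed are
bit-identical.

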