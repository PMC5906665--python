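# glycoflav

Rule-based MS/MS annotation of glycosylated flavonoids, plus the statistics
of a UV-B stress metabolomics/transcriptomics workflow (Pareto-scaled
PCA/OPLS-DA with VIP prioritization, time-course fold-change clustering, and
differential-expression filters).

## Who this is for

Plant metabolomics groups profiling flavonoid glycosides by positive-mode
LC-ESI-MS/MS. Manual elucidation of these compounds follows well-known
arithmetic on neutral losses; `glycoflav` turns that expert procedure into a
deterministic, testable algorithm, and bundles the downstream statistics a
stress time-course study needs.

## The annotation model

A precursor is treated as an `[M+H]+` ion. For every flavonoid aglycone A in
the dictionary, the mass budget `precursor − [A+H]+` is decomposed into at
most two glycosyl residues and one acyl group, and each arithmetically valid
structure (bare aglycone, O-mono, C-mono, di-C,C, C,O-di, and acylated
variants) predicts a fragment pattern:

* **O-glycosides** lose whole residues — hexose 162.0528, pentose 132.0423,
  deoxyhexose 146.0579 Da — exposing the protonated aglycone;
* **C-glycosides** cannot shed the sugar completely: they show cross-ring
  (partial) losses of 90/96/120/150 Da (hexose) or 60/90/120 Da (pentose),
  plus successive water losses, counted from the precursor and from the
  C-core ion that remains after the O-side departs;
* **acyl decorations** travel with their sugar (malonyl +86.0004 Da) or give
  diagnostic marker ions (feruloyl m/z 177.05, coumaroyl m/z 147.04);
* for two C-linked sugars, both rings cleave simultaneously, giving combined
  losses such as −150−90 and −150−120.

Observed fragments are scored against each prediction (aglycone ion 3,
whole-residue loss 2, acyl marker 2, partial loss 1 — halved for the
ambiguous 90/120 losses shared by both sugar series — water 0.5; penalties
for unexplained losses > 40 Da and for missing primary ions), and the
best-scoring structure wins with deterministic tie-breaking. Aglycones of
identical elemental composition are reported together as a candidate set:
mass spectra cannot tell them apart, and neither does the comparator used in
the tests.

## Worked example

Annotate the packaged metabolite table's acylated C,O-diglycoside at
m/z 801.2243 (fragments 463.1, 397.1, 367.1, 177.1, 343.1, 313.1):

```python
from glycoflav.spectra import load_table1_fixture
from glycoflav.annotate import annotate, canonical_name

rec = next(r for r in load_table1_fixture()
           if abs(r.precursor_mz - 801.2243) < 1e-4)
ann = annotate(rec.to_spectrum())
print(canonical_name(ann), ann.glyco_class, ann.score)
for e in ann.evidence:
    print(f"  {e.kind:18s} observed m/z {e.observed_mz:8.1f}")
```

prints

```
C-hexosyl-chrysoeriol O-feruloylhexoside acylated-C-O 5.499
  whole-sugar-loss   observed m/z    463.1
  partial-sugar-loss observed m/z    367.1
  partial-sugar-loss observed m/z    343.1
  partial-sugar-loss observed m/z    313.1
  acyl-marker-ion    observed m/z    177.1
```

Reading: the 338.1-Da loss to m/z 463.1 is a feruloyl-hexose leaving as one
O-linked block; 367.1/343.1/313.1 are −96/−120/−150 cross-ring losses from
that C-hexosyl core, so the remaining hexose is C-linked; m/z 177.1 is the
feruloyl marker ion. The candidate set also lists methylluteolin, the
isobaric methoxy-isomer of chrysoeriol that mass evidence cannot exclude.

The same flow runs from the shell:

```sh
glycoflav synth spectra --seed 1 --out spectra.mgf
glycoflav annotate --input spectra.mgf --out annotations.tsv
glycoflav run-all --seed 1 --outdir out/   # full synthetic pipeline
```

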