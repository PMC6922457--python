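# voicetp

Statistical analysis of the **melody** (highest-pitch) and **bass**
(lowest-pitch) lines of polyphonic keyboard scores, in the tradition of
corpus studies of musical statistical learning.  Given MusicXML scores and a
manifest, `voicetp`:

1. extracts, for every onset, the highest and lowest pitch playable at that
   moment (grace notes excluded, duplicate simultaneous pitches counted once,
   tied notes merged);
2. encodes each line as transposition-invariant interval patterns (+1 per
   semitone up, −1 per semitone down, relative to the pattern's first tone),
   removing the effect of key and key changes;
3. fits order-0..5 Markov (n-gram) models of transitional probability,
   pooling movements/pieces into aggregation units by weighted averaging;
4. derives information content and conditional entropy, and analyses the
   resulting distributions with correlation-matrix PCA and melody-vs-bass /
   major-vs-minor entropy correlations.

It is intended for computational musicology and auditory-cognition
researchers who want these corpus statistics reproducible and testable: a
seedable synthetic two-voice corpus generator with closed-form ground truth
is part of the package, so every stage can be verified without any external
scores.

## Model

For a sequence of encoded events, the order-*n* model is the conditional
(transitional) probability of the next element given the preceding *n*
elements,

    P(e_{n+1} | e_n)  =  P(e_{n+1} ∩ e_n) / P(e_n),

estimated by maximum likelihood (raw count ratios, no smoothing).  The
information content of one observed transition is its surprisal

    I(e_{n+1} | e_n)  =  log2 ( 1 / P(e_{n+1}|e_n) )   [bits],

and the uncertainty of a fitted distribution is its conditional entropy

    H(B|A) = − Σ_i Σ_j P(a_i) P(b_j|a_i) log2 P(b_j|a_i)   [bits],

with context weights P(a_i) equal to each context's share of transitions.
PCA is run on the correlation matrix of (unit, voice) variables over
transition types, retaining components with eigenvalue > 1; Pearson
correlations get two-sided p-values from t = r·√((n−2)/(1−r²)) with n−2
degrees of freedom, and |r| is banded as strong (≥ 0.7), moderate (≥ 0.4),
weak (≥ 0.2).

## Worked example

Generate a synthetic 24-key corpus (12 major + 12 minor units, 20 short
pieces per unit, cross-voice uncertainty correlation 0.8) and analyse it:

```sh
cat > spec.yaml <<'EOF'
layout: study2
n_units: 24
tones_per_voice: 960
pieces_per_unit: 20
interval_alphabet: [-2, -1, 0, 1, 2]
base_concentration: 1.0
uncertainty_correlation: 0.8
seed: 5
EOF
voicetp synth --spec spec.yaml --out corpus
voicetp analyze --manifest corpus/manifest.csv --template study2 --orders 0-3 --out results
```

`results/correlations.csv` begins:

```
# voicetp 0.1.0 config=1eec35116052
analysis,order,voice_or_pair,n,r,p,strength,significant_at_0.05
melody_vs_bass,0,major,12,0.168826,0.599920,none,False
melody_vs_bass,0,minor,12,0.681171,0.014730,moderate,True
melody_vs_bass,1,major,12,0.168826,0.599920,none,False
melody_vs_bass,1,minor,12,0.681171,0.014730,moderate,True
melody_vs_bass,2,major,12,0.155804,0.628718,none,False
melody_vs_bass,2,minor,12,0.777665,0.002905,strong,True
melody_vs_bass,3,major,12,0.143839,0.655607,none,False
melody_vs_bass,3,minor,12,0.775212,0.003055,strong,True
major_vs_minor,0,melody,12,-0.056286,0.862068,none,False
major_vs_minor,0,bass,12,0.231259,0.469563,weak,False
```

Each row is one Pearson test across the 12 units of a mode: at order 2 the
minor-key melody and bass entropies correlate at r = 0.78 (p = 0.003,
strong) — the cross-voice coupling built into the generator — while at n = 12
the major split happens to come out weak for this seed, a reminder of how
noisy r is at this sample size.  Orders 0 and 1 print identical rows because
under the default window encoding both reduce to the elementary-interval
marginal (see `docs/methods.md`).  The tonic-paired major-vs-minor rows
hover near 0: the generator gives the two modes independent structure.

`results/pca_eigenvalues.csv` starts with the order-0 decomposition of the
48 (unit, voice) variables:

```
order,component,eigenvalue,variance_pct,cumulative_pct
0,1,46.266744,96.389049,96.389049
0,2,1.109230,2.310895,98.699944
```

PC1 carries 96% of the variance — all 48 columns share the corpus-wide base
distribution — and eigenvalues sum to 48, the number of variables.
`entropy.csv`, `pca_loadings.csv`, `tp_long.csv` and `components.json`
complete the output; every file carries a config hash and reruns are
byte-identical.

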