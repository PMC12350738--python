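# mpolykit

Degree-based topological indices via the M-polynomial, closed-form
parametric results for polysaccharide repeat-unit families, and a QSPR
regression study linking those indices to ADME-related physico-chemical
properties of drugs.

## Who this is for

Chemical graph theorists and cheminformaticians who work with
hydrogen-suppressed molecular graphs (heavy atoms as vertices, bonds as
edges, bond order discarded) and want:

* exact, rational-arithmetic computation of the classical degree-based
  indices from edge lists or adjacency matrices;
* the M-polynomial operator calculus as an independent cross-check on the
  per-edge closed forms;
* affine closed-form index expressions for polymer repeat-unit families
  (dextran and chitosan are built in), audited against published values;
* a small, reproducible QSPR study (OLS / ridge / lasso / elastic net /
  SVR with cross-validation and external hold-out) on a packaged table of
  45 polycyclic drugs.

## The mathematics in brief

For a graph *G* let *m<sub>ij</sub>* count the edges whose endpoint degrees
are (*i*, *j*), *i* ≤ *j*. The M-polynomial is

> M(G; x, y) = Σ<sub>i≤j</sub> m<sub>ij</sub> x<sup>i</sup> y<sup>j</sup>.

Each degree-based index is simultaneously (a) an edge sum
Σ m<sub>ij</sub> · f(i, j) for a per-edge kernel *f*, and (b) the value of
an operator pipeline applied to M and evaluated at x = y = 1, built from
D<sub>x</sub> = x ∂/∂x, D<sub>y</sub> = y ∂/∂y, their integral inverses
I<sub>x</sub>, I<sub>y</sub>, the diagonal substitution J: y := x, and the
shift Q<sub>α</sub>: multiply by x<sup>α</sup>. The ten indices covered:

| index | kernel f(i, j) | pipeline |
|---|---|---|
| first Zagreb M₁ | i + j | (D<sub>x</sub>+D<sub>y</sub>) M \|₁ |
| second Zagreb M₂ | i·j | D<sub>x</sub>D<sub>y</sub> M \|₁ |
| modified second Zagreb ᵐM₂ | 1/(i·j) | I<sub>x</sub>I<sub>y</sub> M \|₁ |
| general Randić R<sub>α</sub> | (i·j)<sup>α</sup> | D<sub>x</sub><sup>α</sup>D<sub>y</sub><sup>α</sup> M \|₁ |
| symmetric division SDD | (i²+j²)/(i·j) | (D<sub>x</sub>I<sub>y</sub>+I<sub>x</sub>D<sub>y</sub>) M \|₁ |
| harmonic H | 2/(i+j) | 2 I<sub>x</sub> J M \|₁ |
| inverse sum indeg I | i·j/(i+j) | I<sub>x</sub> J D<sub>x</sub>D<sub>y</sub> M \|₁ |
| forgotten F | i²+j² | (D<sub>x</sub>²+D<sub>y</sub>²) M \|₁ |
| redefined third Zagreb ReZG₃ | i·j·(i+j) | D<sub>x</sub>D<sub>y</sub>(D<sub>x</sub>+D<sub>y</sub>) M \|₁ |
| augmented Zagreb AZI | (i·j/(i+j−2))³ | I<sub>x</sub>³ Q₋₂ J D<sub>x</sub>³ D<sub>y</sub>³ M \|₁ |

Both routes are implemented and required to agree; all arithmetic is exact
(`fractions.Fraction`), with decimals appearing only at the presentation
layer. AZI is undefined on an edge joining two degree-1 vertices — that is
raised as an error, never skipped.

For a polymer family whose edge-class counts are affine in the number of
repeating units (dextran: parameter *s*, |E| = 48s − 1; chitosan:
parameter *p*, |E| = 24p − 1), every index with a rational kernel has an
affine closed form, derived here from the partitions and audited against
published coefficient tables.

## Worked example

Indices of acetaminophen's hydrogen-suppressed graph (11 heavy atoms,
11 bonds), from a plain-text edge list:

```bash
$ mpolykit indices acetaminophen.edges
graph_id,M1,M2,mM2,H,ReZG3,SDD,I,F,AZI,R_alpha(alpha=-1/2)
acetaminophen,50,53,2.5,4.9,248,27,11.45,124,74.125,5.1815
```

M₁ = 50 is the sum of endpoint-degree sums over the 11 edges; AZI = 74.125
is exactly 3·(3/2)³ + 6·(6/3)³ + 2·(4/2)³ from the partition
{(1,3): 3, (2,3): 6, (2,2): 2}.

Closed forms for dextran, audited against the published coefficients:

```bash
$ mpolykit family --name dextran
family dextran: |V| = 44*s, |E| = 48*s - 1
M1(s) = 240*s - 6 [MATCH]
M2(s) = 293*s - 10 [MATCH]
ReZG3(s) = 1560*s - 52 [MATCH]
F(s) = 648*s - 14 [MATCH]
mM2(s) = 343/36*s + 1/12 [MATCH]
SDD(s) = 114*s + 1/3 [DISCREPANT (published 871/2*s + 1/3)]
H(s) = 99/5*s - 3/10 [MATCH]
I(s) = 3379/60*s - 19/10 [MATCH]
```

The SDD row is a genuine inconsistency in the published material: the
partition the closed form is claimed to follow from yields slope 114, not
871/2. The audit reports both rather than silently adopting either.

Regression of molecular weight on {ᵐM₂, ReZG₃} over the packaged 45-drug
table:

```bash
$ mpolykit qspr --target MW --models ols --seed 1
Context,Model,Target,R_cv,...
cv,ols,MW,0.9836903915515031,...
external,ols,MW,...,0.9127699702054892,...
ols: MW = 2.2021 + (56.0442)*mM2 + (0.0500)*ReZG3
```

R<sub>cv</sub> ≈ 0.984 is the Pearson correlation between observed MW and
pooled 5-fold out-of-fold predictions; the external row scores a 20%
hold-out refit. The equation shows raw-scale coefficients (standardization
is undone before reporting).

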