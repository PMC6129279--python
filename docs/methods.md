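# Methods

## The correspondence model

Many classes in phenotype ontologies (MP for mouse, HPO for human) carry
formal Entity–Quality (EQ) definitions: the phenotype is an abnormality of
an entity — here, a Gene Ontology biological process — qualified by a
direction.  *Increased thymocyte apoptosis* (MP:0009541), for example, is
defined over the entity *thymocyte apoptotic process* (GO:0070242) with the
quality *increased rate* (PATO:0000912), further constrained by *abnormal*
(PATO:0000460) to separate the pathological phenotype from physiological
variation.  Symmetrically, GO defines regulation classes logically:
*positive regulation of B cell apoptotic process* (GO:0002904) is
*biological regulation* and `positively_regulates` some *B cell apoptotic
process* (GO:0001783).

phenorules joins these two axiom families under one biological hypothesis:
an (unconditional) loss of function in a gene product removes its
regulatory contribution.  Three meta-rules follow:

1. **inc_dec** — if a gene product is annotated with a class that
   positively regulates process *P*, its loss of function predicts the
   phenotype *decreased P*.
2. **dec_inc** — negative regulation of *P* predicts *increased P*.
3. **abnormal** — involvement in *P* predicts *abnormal P*.  This rule is
   unconditional on regulation structure: it fires for every abnormal-
   direction EQ class, whether or not any regulator of the entity exists.

Mirroring the sign/direction combination (positive regulation paired with
an *increased* phenotype, negative with *decreased*) yields inconsistency
patterns: class pairs whose co-annotation to one gene contradicts the
hypothesis and therefore flags a candidate curation error.

Rules and patterns are generated strictly at the class level.  No
propagation along the phenotype hierarchy is applied during generation,
because an annotation *inferred* to a general phenotype (via a subclass
assertion) does not carry the same force as a direct assertion: *decreased
susceptibility to neuronal excitotoxicity* entails *decreased apoptosis*
taxonomically, but not that apoptosis is broadly decreased in the organism.
The consistency checker therefore defaults to exact matching; its
`inferred` mode (subclass matching on the phenotype side, with the asserted
subclass reported) is available but treated as a weaker screen.

## Inputs and filtering

Function annotations are read from GAF 2.x.  Only experimental/curated
evidence codes (EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC) are kept by default;
NOT-qualified rows are dropped, and rows with a non-empty annotation
extension (column 16) are dropped as context-specific — the closest
machine-checkable reading of "conditional on cell type, tissue or stage".
Only biological-process records (aspect P) feed the rule engine by default;
the rules are defined over processes.  Phenotype annotations come from the
MGI gene–phenotype report layout, the HPO gene–phenotype layout, or a plain
two-column TSV; externally predicted functions arrive as a
(gene, class, score) TSV with scores in (0, 1], used unchanged as
prediction confidences, while experimental annotations predict at 1.0.
STRING-style interaction files are filtered at combined confidence ≥ 300
(inclusive), self-pairs removed, pairs canonicalized as (min, max).

Ontologies are read from OBO 1.2/1.4; `intersection_of` tag groups supply
the logical definitions for both the regulation and the EQ patterns.  Only
`is_a` participates in ancestor/descendant closure (subclass-based
inference is the only inference the method relies on); closure is
reflexive.  Obsolete terms are dropped with a warning.  Nested quality
expressions are represented by pre-composed quality classes declared in a
quality configuration: the direction-defining PATO classes are
configurable, with only *increased rate* (PATO:0000912) and *abnormal*
(PATO:0000460) built in as defaults; decreased-rate qualities must be
declared explicitly because their identifiers vary across ontology
releases, and guessing them silently would misdirect rule generation.

## Similarity and evaluation

Information content is computed over genes: `IC(c) = -ln p(c)` with `p(c)`
the fraction of annotated genes carrying `c` after closure, so any class
covering all genes has IC 0.  The natural logarithm is a free choice — any
base rescales all ICs uniformly and cannot change rankings.  Resnik
similarity of two classes is the IC of their most informative common
ancestor, 0 when no common ancestor carries IC.  Gene–gene similarity is
the Best-Match-Average over the genes' direct phenotype sets:

    sim(A,B) = ( avg_a max_b s(a,b) + avg_b max_a s(a,b) ) / 2 .

Normalization divides the whole matrix by its global maximum, so scores lie
in [0, 1] and can be used directly as interaction-prediction confidences;
self-pairs populate the diagonal but are excluded from pair rankings.

Predictions are scored with Fmax over a 0.00–1.00 grid in steps of 0.01.
Truth sets and at-threshold predicted sets are both closure-propagated
before counting (set membership over the ontology is what precision and
recall count; a `propagate_predictions=False` flag reproduces the raw-set
variant), and ontology roots are excluded from both sets because closure
predicts them trivially.  Precision at a threshold is averaged over the
genes with at least one prediction at that threshold; recall over all genes
in the evaluation set (genes with at least one asserted annotation and at
least one prediction).  ROC AUC for interaction prediction uses the
midrank Mann–Whitney convention for ties; the test suite checks it against
a brute-force pairwise comparison count.

## Synthetic fixtures: what they emulate, and what they do not

The generator builds a GO-like ontology (random `is_a` DAG grown by
sampling parents among already-created classes, which guarantees
acyclicity), regulator classes each carrying exactly one regulation
differentia over a distinct target, and a phenotype ontology with an
abnormal/increased/decreased EQ triple per covered process.  The abnormal
layer mirrors the process hierarchy, and increased/decreased classes sit
under their abnormal sibling, giving the similarity measures a meaningful
MICA structure.  Default conditions — 50 processes, 20 positive and 20
negative regulators, full EQ coverage, 100 genes, 10% phenotype noise, 10%
of genes with a planted rule-violating pair — are the scale at which every
downstream property is exercised while the whole suite stays in the
sub-second range.

Each gene's phenotypes are generated *by applying the rules* to its
sampled functions, so consistency is planted by construction and the plant
log is a complete oracle.  Two generator constraints keep that oracle
exact: a regulator regulates exactly one target, and a gene never draws an
inc_dec and a dec_inc rule over the same process (the combination would
realize a genuine, but unlogged, inconsistency pattern).  With noise
enabled, flagged findings are asserted to be a superset of the planted
pairs rather than equal.

What the fixtures do **not** emulate: the topology and depth of the real
GO/MP/HPO (fixture DAGs are shallow and uniform), annotation-count
distributions (real corpora are heavy-tailed), cross-species integration
(a single phenotype namespace stands in for the MP/HPO merge), and curation
artifacts.  Passing tests therefore demonstrate algorithmic correctness —
joins, closures, metrics, plumbing — not the empirical hit-rates obtainable
on release-pinned public corpora, which depend on ontology versions and
curation coverage.

## Numerical and design choices

- Determinism everywhere: fixture generation is byte-identical under a
  fixed seed; rule/pattern serialization is sorted; duplicate predictions
  collapse to the max score with lexicographic tie-breaks.
- Prediction dedup is per (gene, phenotype): scores are confidences, and
  max aggregation preserves the (0, 1] contract where summing would not.
- The regulation index accepts any genus by default (trimmed ontologies
  often omit it); a genus filter restores the strict *biological
  regulation* reading.  Sign-neutral `regulates` definitions contribute to
  no rule.
- Degenerate inputs fail loudly: empty corpora for IC, empty class sets for
  BMA, empty evaluation sets for Fmax, and one-class ROC inputs all raise
  rather than return a default.
- The pipeline writes a manifest with SHA-256 checksums of all inputs and
  outputs; reruns on identical inputs are checksum-identical.

## Known limitations

Only the three meta-rules are implemented; mining further rule templates is
out of scope.  The OBO reader handles the tags the method needs
(`id`, `name`, `is_a`, `relationship`, `intersection_of`, `is_obsolete`)
rather than the full OBO specification, and no OWL reasoning is performed —
regulation classes lacking an asserted `intersection_of` definition are
invisible to the index unless the relationship-edge fallback is enabled.
Conditional/contextual annotations are excluded rather than modelled.
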