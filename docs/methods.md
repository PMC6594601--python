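# Methods

## The comparison model

`herblink` treats the similarity of two historical herbarium collections
as a per-unit ordinal classification problem. A *comparison unit* of the
query collection — by default one distinct taxon (specimens sharing a
normalized determination), optionally one specimen — is scored against
every specimen of a target collection and assigned the level of its most
similar counterpart:

* **100 (exact)** — some target specimen has the same species and exactly
  the same original name(s).
* **75 (large)** — same species, largely the same names.
* **50 (partial)** — same species, partly the same names.
* **25 (vague/coincidental)** — three sub-cases, recorded as rationale
  branches: the name occurs on a specimen of a *different* species (D1);
  the species occurs under a roughly similar or different name (D2); or
  name and species both occur in the target but on different specimens
  (D3, "cross-assigned").
* **0 (none)** — neither the species nor any name occurs in the target.

Branches A/B/C correspond to 100/75/50, E to 0. The assignment is
asymmetric by design: target specimens with no query counterpart are
ignored, because the compared collections differ hugely in size and
purpose (life-long working collections vs one-off presentation volumes),
which would dominate any symmetric presence/absence index.

Assumptions: determinations on both sides are modern, comparable
binomials (species equality is string equality of the normalized
`genus epithet`); names attached to a specimen are an unordered set of
alternatives; and the best counterpart suffices — no global one-to-one
assignment across units is attempted, so a single target specimen may be
the counterpart of several query units.

## Name normalization and matching

Raw names are lowercased; `v→u`, `j→i`, `y→i`; ligatures `æ/œ → ae/oe`;
diacritics folded; punctuation stripped. Qualifier words from an editable
marker lexicon ("vulgo", "quibusdam", "ab aliquibus", "alius", "aliud",
"species", …) are removed from the token sequence and recorded, as are
conjunctions ("seu", "sive", "vel", "et", "over"). Author citations are
detected from a lexicon of inflected forms (Fuchs/Fuchsii, Plinii, …).
Normalization is idempotent. Greek-script names are kept untransliterated
and never matched against Latin-script names — writing Greek characters
was itself a collector's signature habit, so a cross-script "match" would
erase exactly the signal a comparison should expose.

Two names are graded on the ladder `exact > variant > partial > none`:

* *exact* — identical token sequences after normalization;
* *variant* — same token count, every aligned pair within Levenshtein 1;
* *partial* — the principal (first non-marker) tokens agree at exact,
  variant, or declension-stem strength (equal stems after stripping one
  of `-um -us -ae -on -a -i`; minimum stem length 2 so that *Aron* and
  *Arum* reach their shared stem `ar-`), but the names as wholes do not;
* *none* — otherwise.

A declension-suffix-only difference (*Erisimi* ~ *Erysimum*) is
deliberately graded *partial*, not *variant*: a changed ending often
marks a genuinely different phrase construction ("Erisimi species" = "a
kind of Erysimum"), so it counts as shared evidence but not as "the same
name". Levenshtein distances are computed with `edlib`; a fixed suffix
table rather than a Latin morphological analyzer keeps the behaviour
deterministic and auditable. The variant budget of 1 keeps attested
distinct names like *Robertina*/*Albertina* (distance 2) apart.

Name *sets* are matched greedily one-to-one on descending grade
(exact=3, variant=2, partial=1), with index order breaking ties; greedy
matching is exact here in practice because grades are coarse and name
sets tiny (1–6). The category of the pair of sets is: *exact* when both
sides are fully matched at ≥ variant strength with equal set sizes
(orthographic variants still count as "exactly the same name");
*largely* when the matched fraction of query names ≥ θ_L with at least
one exact/variant match; *partly* for any other non-zero matched
fraction; *roughly* when nothing matched but some principal stems are
within one edit; *different* otherwise. The roughly/different split only
labels the D2 branch and never changes a level.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `theta_largely` | 2/3 | minimum shared-name proportion for "largely" |
| `variant_max_edits` | 1 | Levenshtein budget for spelling variants |
| `suffixes` | `-um -us -ae -on -a -i` | declension-equivalence set |
| `min_stem_len` | 2 | shortest stem a suffix may be stripped to |
| `roughly_max_stem_edits` | 1 | stem distance for the "roughly" signal |
| `undetermined_policy` | `non_match` | undetermined specimens never match by species |

θ_L = 2/3 is the smallest simple threshold at which the attested
four-name *Barbarea vulgaris* example (3 of 4 names shared, one at stem
strength) lands at level 75, while a one-of-two match stays at 50; the
exact proportions used in the original desk study were not published, so
the threshold is exposed in configuration and echoed into every report.
Ties between equally similar counterparts break on higher query-name
coverage, then lower target specimen number, making results independent
of row order. With two targets ("combined" mode) each unit keeps the
better of its per-target verdicts, so adding a target can never lower a
level.

## The synthetic generator

`synthetic.generate_pair` emulates the data regime the comparison is
meant to discriminate: two collections drawing on a shared species pool
in which every species carries a small lexicon of period names, where
*common origin* means copying name choices rather than merely sharing
species. Events, in order:

1. each query species enters the target with probability
   `p_shared_species` (default 0.85);
2. a shared species copies the query's exact name choices with
   probability `rho_common_origin` (default 0.7), else re-draws a random
   subset of its lexicon;
3. with `p_extra_name` an extra lexicon name is appended on the target
   side (emulating names accumulated over time — the main reason real
   exact matches degrade to "largely");
4. with `p_duplicate` (default 0.1) the target gains a duplicate specimen
   with independently re-drawn names;
5. with `p_cross_assign` two pure-copy target specimens of different
   species swap their name lists, creating true cross-assignment (D3)
   structure;
6. every token on *both* sides independently suffers one orthographic
   edit with probability `p_mutation` — either a glyph swap from the
   unification set (recoverable by normalization) or a random letter
   substitution. One edit stays within the variant budget; noise becomes
   unrecoverable mainly when both copies of a token drift.

Ground truth is assigned generatively — from which event fired, plus
plain string-identity set logic on the realized name lists — never by
running the classifier, so validation is not circular. Generated
principal tokens are kept globally separated (pairwise edit distance ≥ 2,
distinct stems ≥ 2 edits apart), which makes the string-identity truth
and the fuzzy classifier provably coincide at zero noise; the default
sizes (60 species, 40 query and 80 target specimens) give every level a
non-trivial share of units while keeping a full validation run under a
quarter second.

What the generator does **not** model: historically plausible species
composition, name-lexicon overlap *between* species (real multi-species
genera share name stems — precisely the source of the real data's
25%-level units), collection growth over time, or transcription noise in
determinations. Passing validation therefore shows the classifier
implements its rules faithfully and degrades sensibly under orthographic
noise — not that real 16th-century collections are classified with any
particular accuracy.

## Validation and numerical choices

* **Conservation** — the five level counts of every profile sum to the
  number of units (property-tested over 200 random synthetic
  comparisons in both unit modes).
* **Oracle equivalence** — a brute-force enumerator of all pair rules
  reproduces the incremental classifier's level, branch and counterpart
  on 100 random pairs with up to 15 specimens a side.
* **Identity / emptiness** — self-comparison yields 100% exact;
  collections with disjoint species and lexicons yield all zeros.
* **Recovery and monotonicity** — zero-noise agreement with ground truth
  is exactly 100%; over 30 fixed-seed replicates per setting, the mean
  assigned level is non-decreasing in ρ (allowance 0.5 level points on
  the 0–100 scale for replicate-mean jitter) and agreement is
  non-increasing in `p_mutation` (allowance 0.01).

Degenerate inputs: empty target collections and taxon mode without any
determination raise errors; marker-only names (a bare "alius") are
excluded from name sets and never match; undetermined query specimens
are classified with species forced to non-match (configurable to exclude
them instead); missing mapped columns, duplicate specimen numbers and
empty name fields fail loudly with the offending column or row.

## Curated-table tallying

`read_assignments` + `tally_levels` load an externally curated per-unit
similarity table (CSV/TSV/XLSX) and tally its level column, for auditing
published profiles whose per-unit assignments were made by hand. The test
suite exercises this path on synthetic stand-in tables only; re-deriving
hand-made assignments from raw names with this package's default
thresholds is expressly not claimed to reproduce them unit-for-unit.

## Known limitations

* Phrase-name alignment is order-preserving token-by-token; genuinely
  reordered polynomials ("Lychnis sylvestris" vs "Sylvestris lychnis")
  grade lower than a human would judge.
* The suffix table covers the common nominative/genitive endings only;
  oblique cases and Greek-latinized endings (-os/-es) fall back to the
  edit-distance layer.
* Vernacular detection relies on a small Italian token list plus the
  "vulgo" marker; untagged vernacular names in Latin spelling pass as
  Latin.
* In taxon unit mode, multi-determination query duplicates collapse to
  one unit per determination; how the original study counted such cases
  is unknown, so both unit modes are exposed.
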