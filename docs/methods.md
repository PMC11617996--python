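# Methods

This note documents the models and procedures implemented in `hdlstruct`,
the parameters that matter, the design choices made where conventions
diverge, and what the synthetic-data validation does and does not show.

## Coordinates and sequences

All residue coordinates are mature-chain positions (signal and propeptide
removed), 1-based. The bundled FASTA fixtures are the mature human APOA1
chain (243 aa; accession P02647) and mature APOA2 chain (77 aa; P02652).
Inputs carrying precursor numbering must be trimmed by the caller; the
package never guesses an offset.

The default APOA1 helix annotation is the consensus 11/22-mer
decomposition into ten amphipathic repeats: H1 44–65, H2 66–87, H3 88–98,
H4 99–120, H5 121–142, H6 143–164, H7 165–186, H8 187–208, H9 209–219,
H10 220–243. Residues 1–43 form the globular N-terminal segment and are
deliberately reported as "unassigned" by `annotate_residue`; the
boundaries are an external convention, not a measurement, and any
`HelixAnnotation` can be substituted.

## Mass arithmetic

Peptide masses are sums of residue masses plus one water, from
monoisotopic and average residue tables kept in `proteins`. The tables are
cross-checked in the test suite against an independent calculator
(pyteomics). A disulfide-linked homodimer weighs twice the chain minus two
hydrogens per bond; for mature APOA2 with one inter-chain disulfide this
gives 17.4 kDa (average masses), the textbook value.

Cross-linker chemistry is a registry of spacer deltas (monoisotopic Da):
BS3 138.06808 (C8H10O2 after both amide bonds form), BS3-D12 adds exactly
12 × (m_D − m_H) = 12.075324, DSBU 196.08479 (C9H12N2O3), DSSO 158.00376
(C6H6O3S). A mono-link (one hydrolyzed end) adds the spacer delta plus one
water; this identity is asserted at registry load. A cross-linked species
at charge z weighs m(α) + m(β) + Δ + z·1.0072765 Da; the package always
stores neutral mass plus charge. The published species masses are
reproduced at z = 3 (BS3 light/heavy) and z = 4 (DSBU) — the printed
tables do not state charges, so these are inferences validated by
agreement within ≤ 0.03 Da. One documented discrepancy: the published
BS3-D12 mono-link value (168.1528 Da) differs from the chemical value
Δ + water + 12×(m_D − m_H) = 168.1540 Da by 1.2 mDa; the implementation
returns the chemical value.

## Digestion and peptide classes

`digest` performs fully specific digestion: cleavage after any residue in
the rule's `cleave_after` set unless the next residue is in
`blocked_next`, peptides bounded by cleavage sites or protein termini,
with at most `max_missed` internal sites. Trypsin defaults to the
classical rule (after K/R, blocked before P) with a `block_proline=False`
variant, since search engines differ and the upstream convention is not
knowable from a peptide table. Proteinase K is modelled as cleavage after
{A, G, I, L, M, P, V, F, W, Y} with no blocking and a 20-missed-cleavage
budget — the nonspecific protease is approximated by its preferred P1
residues, matching how LiP search spaces are configured in practice.

A located peptide terminus is "specific" if the preceding residue is a
tryptic site (and not blocked) or the boundary is a protein terminus;
peptides are tryptic (both specific), semi-tryptic (exactly one), or
non-tryptic. Multi-mapping peptides within a protein take the first
occurrence with a warning.

## LFQ statistics

Processing order is fixed: log2 → missingness filter → median
normalization → imputation → test. The filter keeps a feature if at least
one group observes it in ≥ 50% of samples. Median normalization shifts
each sample additively so its observed median equals the grand median of
the pre-normalization sample medians; log2 fold changes are invariant to
the alternative (subtract each median), so the choice is cosmetic and
made for interpretability of absolute values. Imputation is per sample:
missing entries are drawn from Normal(m − 1.8·s, (0.3·s)²) with m, s the
observed column mean and standard deviation — the standard left-censoring
("downshifted Gaussian") model; width 0.3 and shift 1.8 are the canonical
defaults. One integer seed governs all draws and observed cells are never
altered (asserted bitwise in tests). The test is a two-sample Student
t-test (pooled variance) with a Welch option; thresholds are raw
P < 0.05 (protein level) and P < 0.01 (peptide level) with an optional
Benjamini–Hochberg mode that defaults off, mirroring the raw-threshold
convention of the upstream workflow.

## Structural barcodes

Peptide fold changes are corrected by subtracting the parent protein's
log2 fold change (division in linear space) only when the protein change
is itself significant; otherwise the raw value passes through, and absent
parents pass through with a warning. Only semi-tryptic peptides below the
peptide alpha contribute. In the default `share` mode each covered residue
receives fc/length, so one peptide's contributions sum exactly to its
corrected fold change (conservation is a test invariant); `spread` mode
(full value on every covered residue) is kept because the alternative
reading of "equally distributed across the encompassing amino acids" is
defensible. Residues covered only by non-significant peptides carry value
0 with coverage > 0, distinguishing "tested, unchanged" from "never
covered". Rendering uses a diverging red/blue scale centred at zero
(red = exposed, blue = shielded) under the helix track.

## Cross-link calibration and consensus

`calibrate_threshold` scans candidate score values from best to worst and
returns the lowest threshold at which candidates at or above it include
no more than the allowed number of decoy-protein hits (default 0),
accepting the target-only candidates; minimality is brute-force-verified
in tests. Engine adapters map native scores to a higher-is-better scale
(pLink-style E-values are −log10-transformed); published per-engine
thresholds ship as config presets only.

Consensus works on concrete residue pairs after expanding ambiguous site
alternatives: a pair is reported when pairs within ± `site_tolerance`
residues on both ends occur in at least `min_evidence` distinct evidence
sets, and surviving pairs that match each other within tolerance are
merged into connected components (smallest coordinates as the
representative). On the two bundled table transcriptions this yields 4
pairs at exact matching and 5 at ±1; the implementation is verified
against an independently coded double-loop oracle on random sets.

## Efflux

Percent efflux is 100 × medium dpm / total internalized dpm, with the
denominator taken from medium-only wells (a per-well medium+cell variant
exists, as both conventions occur in the field). Background normalization
subtracts the mean of no-acceptor control wells per condition —
subtraction rather than division, which yields the ~0-based baseline
expected of dose–response plots. Transporter-specific efflux is the
difference of condition means with propagated standard error
√(s₊²/n₊ + s₋²/n₋). Replicates are treated as technical; no nested error
model is fitted.

## Synthetic data

The generators are pure functions of a `SimulationConfig` (seed included)
and emulate the study conditions:

- **LiP**: five replicates per group at doses 0/20/40/80/160% (APOA2 as
  mass-% of APOA1). HDL-bound APOA1 decays exponentially with dose; the
  default rate leaves 5% at the top dose (a 95% drop). APOA2 rises
  saturably. The peptide table contains tryptic (missed ≤ 2, length 6–30)
  and semi-tryptic peptides (tryptic parents truncated at one internal
  Proteinase K site). Planted accessibility windows default to the
  observed response — exposure of the N-terminal segment (1–43), H1 and
  H10, shielding of H7 — at 2.0 log2 units, applied to semi-tryptic
  peptides scaled by overlap fraction, on top of the protein-level change.
  Gaussian log2 noise (sd 0.25) and logistic intensity-dependent dropout
  (midpoint 19, steepness 1.2) produce missing-not-at-random censoring:
  rare at the control intensities, dominant where displacement pushes
  peptides toward the detection limit.
- **XL-MS**: eight true APOA1–APOA2 lysine pairs per run, emitted in two
  independent evidence sets as H12/D12 twins with correct theoretical
  masses at charges 3–5 and scores ~N(5.0, 0.4); decoy candidates sit on
  synthetic random-sequence decoy proteins with scores ~N(2.5, 0.5).
- **Efflux**: transporter-positive wells follow
  baseline + A·(d/p)·exp(1 − d/p), maximal exactly at the peak dose p
  (default 20%); transporter-negative wells are flat; counts carry Poisson
  noise around a ~20,000 dpm total.

What passing recovery tests show: the pipeline's statistics and
bookkeeping correctly invert the generative model (signs and locations of
planted windows, identities of true pairs, position of the response
peak). What they do not show: robustness to features real data has and
the generator lacks — correlated peptide noise, retention-time and
detectability biases, chimeric identifications, partial digestion
kinetics, or biological replicate structure.

Problem sizes used by the validation runs — ~550 peptide features × 25
samples per LiP dataset, 10–20 simulation seeds per recovery estimate,
1,000 random sequences for the digestion oracle — were chosen to make the
statistical checks stable at desk scale.

## Numerical and degenerate-input choices

Identical groups give t = 0 and P = 1 (the NaN from zero pooled variance
is mapped to "no evidence of change"). Median normalization asserts
post-condition equality to 1e-9 on every run. Barcode TSVs are written at
six decimals, and pipeline outputs are byte-identical under a repeated
seed. An empty candidate file yields an empty consensus with a warning,
not an error; an unknown engine or protein id is an error naming the
offender and the registered alternatives. Thresholds, linker deltas and
repeat boundaries are data (config/registry), not code constants, except
where a value is a chemical identity (water, proton, D−H).

## Known limitations

No spectrum-level modelling (search engines are upstream), no FDR beyond
the decoy-protein threshold rule, no peptide→protein roll-up, no 3-D
structure mapping, no isoform or PTM handling, and the helix boundaries
are a literature convention. The `share`/`spread` barcode ambiguity is
exposed rather than resolved.
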