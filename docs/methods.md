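# Methods

## The model

`cd8net` implements a Boolean (logical) model of CD8+ T-cell fate
decisions.  Eighteen regulated nodes — the lineage transcription factors
T-BET, GATA3, RORγT, FOXP3, EOMES and FOXO1; the effector cytokines IFN-γ,
IL-4 and IL-10; the metabolic regulatory module ROS, SOD, Akt, mTORC1 and
mTORC2; and the outputs Granzyme B, GLUT1, BCL-2 and Casp-3 — each carry a
Boolean rule over their regulators.  Seventeen further names appear only on
rule right-hand sides and are treated as inputs, clamped per scenario:
the cytokine signals IL-2s/IL-4s/IL-6s/IL-10s/IL-12s/IL-15s, IFN-γs, type-I
interferon, TGF-β; the metabolic context Glucose, FFAs, Ceramide, EtOH,
amino acids (aa), growth factors (GFs); and the receptor signals PD-1 and
FasL.  A name that is never a rule target cannot be a state variable, which
is why the five signals absent from the source table's input list are
declared as inputs rather than nodes.

State updates follow the classical parallel convention: every node due at
step *t* evaluates its rule on the *pre-step* state joined with the input
clamps.  Two schedules are supported:

* **synchronous** — all nodes due at every step;
* **timed-asynchronous** — node *i* is due when `t mod period_i == 0`.
  Periods derive from a kinetic class per node: metabolite 1, signalling
  complex 2, transcription factor 4, newly expressed protein 4.  The
  original per-node timings are not recoverable from the source text, so
  these class defaults are a documented stand-in preserving the intent —
  fast metabolism, slow transcription — while keeping the dynamics
  deterministic; they are fully overridable per node.

Knock-outs and knock-ins are clamps (`x_i = 0` or `1` at every update,
regardless of rule or schedule).  Initial states are *not* clamped: all
`2^18` configurations are enumerated and clamp-violating initial states
fall into the clamped subspace after one step, so basins remain defined
over the full state space.

## Attractor enumeration

The engine vectorises one update sweep over the whole state space: states
are the integers `0 … 2^18-1`, each node's rule is evaluated once per
phase on bit-columns extracted from the state index, and the results pack
into a successor array per schedule phase.  Composing the phase maps gives
the per-period map `M`; pointer doubling (`r ← r[r]`, ⌈log₂ Ω⌉ times)
lands every state on its terminal cycle, after which cycles are walked
explicitly and basins counted exactly with a single `bincount`.  All basin
arithmetic is integer; frequencies `f_k = 100·y_k/Ω` are derived on
demand and never accumulated in floating point.

Attractor identity must respect schedule phase.  A timed attractor is a
cycle over (state, phase) pairs; two state sequences denote the same
attractor only if one is a *phase-preserving* rotation of the other.  The
canonical form is therefore the lexicographically minimal rotation **by
multiples of the phase count** of the full per-period state sequence laid
out from phase 0.  (Plain rotation-invariance is wrong: random-network
cross-checks surfaced distinct timed attractors visiting the same states
at different phases.)  A "fixed point" is a state invariant at every
phase; anything else is reported as a cycle — cycles are first-class
results, not errors, which is what makes full-convergence statements
testable rather than assumed.

Scaling: an 18-node cell enumerates in ~0.1–0.3 s on one CPU core; the
default refusal ceiling is n = 24 (memory for the successor arrays), above
which users should sample trajectories with `find_attractor` instead.

## Phenotype classification

Fixed points are classified on two axes by Boolean identifiers over the
marker nodes:

* **stage** — Naive `¬(EOMES ∨ TBET ∨ GATA3 ∨ RORγT ∨ FOXP3)`, Effector
  `¬FOXO1 ∧ EOMES ∧ (any master)`, Memory `FOXO1 ∧ EOMES ∧ (any master)`;
* **lineage** — Tc1 `EOMES ∧ TBET ∧ IFNγ ∧ ¬FOXO1 ∧ ¬(others)`, and
  analogously Tc2 (GATA3 ∧ IL-4), Tc17 (RORγT), TcReg (FOXP3 ∧ IL-10),
  else Tc0 when no master is expressed.

The four polarized-lineage identifiers are pairwise mutually exclusive
(each demands a master the others negate; verified exhaustively over all
marker combinations).  Naive and Tc0 are logically identical — the same
cell read on different axes — and are never double-counted.  A
memory-stage attractor cannot match a polarized identifier (those require
FOXO1 off), so its lineage is additionally inferred from master-regulator
identity and reported with stage Memory; the strict lineage axis keeps
such mass under `unclassified` so that the lineage labels plus
`unclassified` always partition Ω exactly.  "FOX03" in the source TcReg
identifier is read as FOXP3: the network declares no FOXO3, and TcReg is
FOXP3-defined.  Cycles are unclassified by construction.

A fixed point is *classified* when it matches at least one identifier on
either axis.  The per-cell "classified fixed-point mass" — the basin
percentage ending in classified fixed points — is the quantity behind
full-convergence statements and is what `scripts/acceptance.py` reports.

## The two rule variants and the repair manifest

The source rule table is visibly damaged: five of eighteen rows (GATA3,
IL-4, RORγT, FOXP3, EOMES) open parentheses that never close, and several
tokens are misspelled (`F0X01`, `IFN1`, `Et0H`, bare `IL12`).  The package
therefore ships two variants.

**`verbatim`** applies only what is mechanically forced: operator
precedence NOT > AND > OR, auto-closing of unbalanced groups at end of
expression (each repair logged at WARNING), and token normalisation of the
misspellings.  It is the auditable literal reading, kept for sensitivity
analysis, not the working model.

**`reconciled`** (default) adds six structural repairs, each a first-class
`Deviation` record printable via `cd8net show-model`.  They were selected
by evaluating candidate readings of the damaged/ambiguous rows against the
model's documented qualitative behaviour (the 13-assertion calibration
suite in `cd8net.cd8`), choosing the minimal set under which the suite
scores best under both schedules:

1. **IFN-γ** — the trailing `∧ ¬IL6s ∨ IL4 ∨ IL10` is grouped as
   `∧ ¬(IL6s ∨ IL4 ∨ IL10)`.  The literal reading makes IL-4 alone an
   IFN-γ activator, destroying Tc2 polarization.
2. **IL-4** — the `¬(IFNγ ∨ IL6s)` factor gates the whole rule, so
   exogenous IL-4 signalling is also silenced by IFN-γ.
3. **FOXP3** — the cytokine term reads
   `(IL2s ∨ IL12s) ∧ (TGFβ ∨ FOXP3 ∨ IL4)`; literally, `∨ FOXP3 ∨ IL4`
   float at top level, forcing FOXP3 on under IL-4 alone.
4. **GATA3** — FOXP3 is appended to the truncated inhibitor tail.  Without
   FOXP3 ⊣ GATA3, EOMES drives GATA3 on in every TcReg-bound trajectory
   and TcReg (which requires GATA3 off) is unreachable under IL-4 + IL-12.
5. **EOMES** — the truncated row is completed as
   `(ROS ∨ EOMES ∨ (IFNI ∧ FOXO1) ∨ TBET ∨ GATA3 ∨ RORγT ∨ FOXP3) ∧ ¬mTORC2`:
   the lineage masters drive the shared effector factor EOMES, and mTORC2
   gates the rule.  Every effector/memory identifier requires EOMES, so
   without a master drive half of state space parks in master-on/EOMES-off
   attractors that match no identifier.
6. **mTORC1** — the inhibitory complex is read as `¬(PD1 ∧ IL15s)`.  As
   printed the suppression also requires mTORC2, which itself activates
   only through ROS or growth factors — so mTORC1 could never switch off
   in unstressed cells, FOXO1 would stay off, and no memory state could
   exist in any cytokine context.  (The disjunctive reading
   `¬(mTORC2 ∨ (PD1 ∧ IL15s))` was also evaluated; it creates an
   mTORC1/mTORC2 mutual-inhibition oscillator under metabolic stress that
   destroys the robustness of the TcReg phenotype.)

With these repairs the mechanism chain is coherent: PD-1 and IL-15 jointly
license mTORC1 suppression → FOXO1 can switch on → memory states exist and
depend on both signals; metabolic stressors drive ROS → in the
PD-1/IL-15-licensed context mTORC1 stays off, ROS activates mTORC2, mTORC2
shuts EOMES and FOXO1 → the inflammatory effector and memory programmes
collapse while ROS-knockout or SOD over-expression restores them; TcReg,
generated in a PD-1-free context where mTORC1 stays on and mTORC2 off, is
untouched by every stressor.

## Scenario presets

All presets clamp every input; unnamed inputs default to 0 except IL-15s
(default 1: all conditions run in the presence of IL-15 unless the
condition itself removes it).  PD-1 defaults to 1 in the IL-12 + IFN-γ
presets — its removal is one of the documented comparisons, implying
presence at baseline — and 0 elsewhere; aa and GFs default to 0 (a GFs=1
baseline provably creates an autonomous mTORC1/mTORC2 two-cycle that
contradicts the documented full convergence of the unstressed cells).  The
diabetic context sets Glucose = FFAs = Ceramide = 1 simultaneously.  The
STAT6-null condition clamps GATA3, IL-4 *and IL-10* to 0: all three are
STAT6-responsive in type-2 polarization, and with IL-10 left free the
EOMES ∧ mTORC1 drive forces IL-10 on, IL-10 blocks IFN-γ, and the
documented Tc1 switch cannot appear under any rule reading.

## The synthetic-network module

The study object is a state space, not a dataset, so validation rests on
seeded random Boolean networks (configurable size, in-degree bound, and
rule family: random truth tables, nested-canalizing chains, AND/OR/NOT
trees) plus a library of hand-checkable fixtures.  Every atlas the engine
produces is checked against an independent brute-force oracle that builds
the explicit (state, phase) transition graph, extracts terminal strongly
connected components via graph condensation, and counts basins along the
condensation DAG — deliberately sharing no dynamics code with the engine.
Random networks emulate the *structural* properties the engine must handle
(multiple attractors, long transients, phase-dependent cycles, clamps);
they do not emulate biological network statistics (no scale-free topology,
no criticality tuning), so oracle agreement validates the machinery, not
the biology.

## Numerical and design choices

* Basins, Ω and y_k are exact integers end to end.
* Node order of the source table defines bit positions (bit 0 = T-BET) and
  the order of serialized bit strings.
* `max_steps` for single trajectories defaults to `4·Ω·phases`; exceeding
  it raises (a deterministic finite system must recur — hitting the cap
  signals a bug, never a truncation).
* Atlas rows are sorted by descending basin then canonical key, making
  reports byte-reproducible.
* Enumeration covers internal nodes only; inputs are clamped context, so a
  cell's Ω is `2^18` regardless of how many inputs the condition sets.

## Known limitations

The source rule table, read as printed, cannot reproduce several pieces of
the documented qualitative behaviour; the repairs above fix what a
parenthesization/typo-level repair can fix, and the rest is left visibly
red in the acceptance checks rather than papered over:

1. **Tc17 and Tc1 in the cytokine-free cell.**  Every parenthesization of
   the RORγT row keeps `IL6s ∧ TGFβ` as top-level conjuncts, so RORγT ≡ 0
   — and f_Tc17 ≡ 0 — whenever IL-6 and TGF-β are absent.  Likewise,
   without exogenous IFN-γ/type-I-interferon input, IFN-γ requires its
   self-loop branch (needing mTORC1), while the IL-10 row switches IL-10
   on whenever `EOMES ∧ mTORC1` and IL-10 blocks IFN-γ; since Tc1 requires
   EOMES, f_Tc1 ≡ 0 in the cytokine-free cell under every reading.  Only
   the Tc0-dominance part of that cell's expected behaviour is
   reproducible.
2. **Stressor abolition outside the inflammatory context.**  Stressors
   abolish Tc0 (ROS forces EOMES on) and Tc1 (PD-1/IL-15-licensed mTORC2
   shuts EOMES), but no printed interaction connects ROS or mTORC2 to
   GATA3, RORγT or IL-4 in the PD-1-free presets, where mTORC1 stays on
   and FOXO1 off — stressed Tc2 and Tc17 fixed points survive with large
   basins under every reading explored.
3. **mTORC2 knock-in rescue.**  In the stressed inflammatory context the
   natural attractors already hold mTORC2 = 1 (ROS-driven), and a clamp
   `x_mTORC2 = 1` is dynamically indistinguishable from that natural
   regime — so knock-in rescue and baseline abolition of Tc1 are mutually
   exclusive for any reading.  The ROS-knockout and SOD-knock-in rescues
   and the mTORC2-knockout abrogation (through forced FOXO1) are
   reproduced.
4. **Full synchronous convergence.**  The printed rules contain genuine
   synchronous limit cycles — a lagged IFN-γ → Akt → mTORC1 → IL-10 ⊣
   IFN-γ negative feedback in cytokine-poor cells, and a ROS → SOD ⊣ ROS
   loop interacting with mTORC2/FOXO1 under stressors — so several cells
   retain cyclic or unclassified mass (the stressed inflammatory cells are
   dominated by it).  The unstressed IL-12 + IFN-γ, IL-4 + IL-12 and IL-4
   cells, and the IL-15/PD-1 deprivation cells, do converge to classified
   fixed points over 100.000 % of the state space.

These are properties of the published rule text itself; resolving them
would require information (the original model files and per-node timings)
beyond that text.
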