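# Methods

`gjdock` post-processes molecular-dynamics trajectories of connexin
channels — hexameric hemichannels (HCs), dodecameric gap-junction channels
(GJCs), and two-hemichannel (HC-HC) docking models — to quantify the
geometric interactions through which the extracellular Cys disulfide redox
state governs hemichannel docking. This note describes the models and
procedures, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was open.

## Structures and trajectories

Structures are PDB v3 files; trajectories are multi-MODEL PDB files with a
fixed topology and a constant frame interval (default 10 ps, the recording
interval of the production runs, so a 100 ns run is 10,000 frames). Binary
MD formats are deliberately out of core scope: the analyses operate on
exported PDB frames, which keeps inputs inspectable. Hydrogens are read and
preserved — two of the three H-bond detectors require explicit donor
hydrogens. Atom parsing and formatting are delegated to biotite; insertion
codes are out of scope and only the first altloc is taken.

Because PDB files carry no bond records, a hydrogen is attributed to the
nearest heavy atom within **1.45 Å**. The cutoff must exceed the S–H bond
length (≈1.34 Å, the distance at which thiol hydrogens are placed), while
staying below the shortest non-bonded H–heavy approach in these analyses;
1.45 Å satisfies both. Thiol-hydrogen naming variants across force fields
("HG1" vs "HG") are accepted via a synonym map.

## Residue annotation and constants

All connexin-specific numbering lives in `ConnexinAnnotation` (Cx43,
1-based PDB numbering, inclusive intervals): extracellular loops EL1
47–73 and EL2 177–203; the conserved Cys triads 54/61/65 (EL1) and
187/192/198 (EL2); the internal (55–58) and external (194–196) docking
interface residues; transmembrane spans 20–46, 74–94, 154–176, 205–226;
and the alignment base for RMSD, 21–46, 74–93, 156–176, 204–229. The TM
spans quoted in different contexts differ slightly; the RMSD-specific set
is used only for alignment, and the membrane-positioning set is kept
separately. Every numeric cutoff lives in `AnalysisParameters`, serialized
as YAML, with these defaults:

| parameter | default | role |
|---|---|---|
| `sc_min_seq_separation` | 10 residues | SC criterion 1 |
| `sc_vdw_tolerance` | 1.0 Å | SC contact slack over vdW sum |
| `sc_triplet_min_contacts` | 7 of 9 | SC criterion 3 |
| `sc_flank_width` | 4 residues | flanking tetrapeptide width |
| `sc_min_stability_fraction` | 0.02 | reportable-SC threshold |
| `hbond_HA_cutoff` | 2.5 Å | trans-GJ donor-H to acceptor |
| `cys_cys_SH_cutoff` | 4.3 Å | SG to thiol-H |
| `cys_iface_S_heavy_cutoff` | 4.1 Å | SG to interface heavy atom |
| `cys_iface_H_cutoff` | 3.2 Å | donor-H to partner |
| `clash_cutoff` | 2.0 Å | steric clash (strict <) |
| `ss_bond_SG_SG_cutoff` | 2.3 Å | disulfide read-out |

Van der Waals radii are a Bondi-style heavy-atom set (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å; 1.70 Å otherwise); hydrogens are excluded from
contact and pore computations. The disulfide read-out cutoff of 2.3 Å is a
design choice: a bonded S–S sits near 2.05 Å and the nearest non-bonded
S–S pairs in these systems are beyond 3 Å, so 2.3 Å separates the two
populations with slack on both sides. All cutoffs comparing a distance to
a threshold use strict `<` ("below"), except the disulfide read-out and the
2% stability threshold, which are inclusive ("at least").

## Stabilization centers

Two residues form a stabilization center (SC) when (1) they are at least
10 apart in sequence — pairs on different chains pass this automatically,
since sequence separation is undefined across chains and the trans-GJ SCs
of interest are inter-chain; (2) some heavy-atom pair is closer than the
sum of the two atoms' vdW radii plus 1.0 Å; and (3) one residue can be
chosen from each flanking tetrapeptide of each partner (residues −4…−1 and
+1…+4) to form two triplets {left, residue, right} such that at least 7 of
the 9 cross-triplet residue pairs satisfy criterion 2.

Criterion 3 deserves comment: the phrase "four neighbours … both
directions" and "nine contacts" are only mutually consistent under the
triplet reading above (3×3 cross pairs, one flank residue selected per
side), which is the original SCide definition; that reading is implemented.
A flanking side with no residues (chain terminus) admits no triplet and the
criterion fails; sides with 1–3 residues select among those available.

Detection scans candidate residue pairs (KD-tree prefilter at the largest
possible contact threshold), and the per-frame results aggregate into
stability fractions — the fraction of analysed frames in which a pair is
present. Reportable extracellular SCs contain at least one EL1/EL2 residue
and persist in ≥ 2% of the run. Pairs whose chains lie in the two different
hemichannels (A–F vs G–L, docking register A-J, B-I, C-H, D-G, E-L, F-K)
are trans-GJ SCs and carry a subunit-pair label. All frames are analysed by
default (10 ps granularity); a stride option exists for coarser sampling.

The detector is verified against an independent brute-force implementation
(all residue pairs × all 4×4×4×4 flank selections) on randomized toy
chains; the two agree exactly on every fixture tried.

## Hydrogen-bond categories

Three geometric detectors, mirroring the interaction classes of the docking
analysis:

* **trans-GJ** — between interface residues 55–58 of opposing hemichannels.
  Donor atoms: backbone N, Asn OD1, Thr OG1, Gln NE2; acceptor atoms:
  backbone O, Asn OD1, Thr OG1, Gln OE1; a bond is a (donor-hydrogen,
  acceptor-heavy) pair below 2.5 Å. Asn OD1 is retained in the donor list
  as specified even though an sp2 oxygen normally carries no hydrogen —
  lacking an attached H it simply never donates (a debug notice is logged).
  The cross-hemichannel restriction is the default; intra-HC 55–58 bonds
  can be requested explicitly.
* **Cys–Cys** — thiol interactions of the reduced state: a Cys SG within
  4.3 Å of another Cys' thiol hydrogen. Oxidized Cys (no thiol H) cannot
  donate but remain acceptors.
* **Cys–interface** — a Cys SG (donor or acceptor) against the 55–58
  donor/acceptor atoms, requiring **both** the S–heavy distance below
  4.1 Å and the donor-H distance below 3.2 Å (the criteria are stated
  conjunctively and implemented as such).

Counts can be restricted to the A–F subunits, the convention for comparing
solo-HC runs against dodecameric models; the time-series module also
reports, per chain-agnostic residue-pair label (e.g. "58Q-58Q"), the number
of subunit pairs exhibiting the bond in each frame.

## Disulfide state

The canonical intra-subunit pairings are 54C–198C, 61C–192C, 65C–187C
(Cys(1)–Cys(3), Cys(2)–Cys(2), Cys(3)–Cys(1) of the EL1/EL2 triads; 36
bonds in a dodecamer). `assign_disulfides` sets the state: *closed* records
the three canonical bonds per chain and strips thiol hydrogens; *open*
records none and adds HG1 1.34 Å from SG along the CB-opposed direction
when absent. If that direction is sterically blocked — any other heavy
atom would end up closer to the hydrogen than its own SG, breaking the
nearest-heavy attachment rule (this happens when opening a closed
geometry, where the CB-opposed direction points at the former partner) —
deterministic perpendicular directions are tried and the least-crowded
placement wins. Existing atoms are never moved. `detect_disulfides` reads
the state back from geometry: SG–SG pairs within 2.3 Å.

## Extracellular RMSD

Each frame is superposed onto the first frame on the heavy atoms of the
membrane segment (21–46, 74–93, 156–176, 204–229), then the RMSD of the
extracellular heavy atoms (47–73, 177–203) is computed. Heavy atoms are
used for both alignment and measurement — hydrogens may be absent or
force-field-dependent, and heavy-atom RMSD is the stable convention.
Superposition is the closed-form least-squares rotation (SVD with
reflection correction); collinear point sets are rejected since the
optimal rotation is not unique. Two closed-form checks pin the
implementation: shifting all extracellular atoms by 1 Å with the TM fixed
reads out exactly 1.0 Å, and any whole-frame rigid motion reads out 0.

## HC-HC assembly

`build_hc_hc` superposes two copies of a 6-chain hemichannel onto the A–F
and G–L halves of a 12-chain GJC template, matching chains in alphabetical
order (the rotational register is not dictated by the inputs, so it is
explicit and configurable) with correspondence on shared Cα atoms. The
second copy is relabelled G–L and its serial numbers continue after the
first copy's, giving continuous numbering across the dimer. Steric clashes
across the interface (heavy-atom pairs < 2.0 Å) are reported in the build
log, never resolved — energy minimization belongs to the MD engine, not
this package. `translate_chains` applies exact z-offsets (the 1/3/5 Å
docking-distance series) to one hemichannel.

## Pore profiling

The water-accessible channel is profiled as the maximal inscribed sphere
per axial slice: at each z sample the in-plane centre maximizing

    f(c) = min over heavy atoms a of ( |c − a| − r_vdw(a) )

is found by Nelder–Mead local search seeded from the previous slice's
optimum plus 8 jittered starts (seeded RNG; repeated runs with the same
seed are bit-identical). This is a deliberate simplification of the
classical simulated-annealing sphere-chain approach: it computes the same
quantity (radius vs axial position), is testable against analytic shapes,
and has no tunable cooling schedule. Defaults: step 0.5 Å along +z (the
membrane normal for OPM-aligned structures; other axes are handled by an
internal rotation), radius clamp `r_max` 15 Å. Slices whose optimum
escapes the structure (or with no atoms in reach) are flagged *unbounded*
and excluded from minima. Twice the minimum radius is the minimal channel
diameter; a window-restricted minimum is reported alongside, with the
"extracellular" window defined per frame as the z-extent of the EL1/EL2
residues (the region's bounds are not otherwise defined). On cylinder
fixtures the profile reproduces the analytic inscribed radius (ring radius
minus vdW radius) to well within 0.1 Å, and a planted constriction is
localized at the correct z.

## SC connectivity graph

A run's SC dynamics collapse into one residue-level graph: nodes are
chain-aggregated residue labels ("65C"), node weight counts SC
participations over all subunit instances, an edge is an observed SC
between two residue positions, and edge weight is the stability fraction
averaged over instances (mean rather than max — the aggregation is not
dictated, and the mean is the less outlier-sensitive choice). Cys nodes
are flagged. The handshake identity Σ(node weights) = 2 × Σ(edge instance
counts) holds by construction and is asserted in tests. Cys-centred
connectivity modules are exposed as connected components above a node-
weight threshold — a deliberately simple read-out, since the module
structure is a visual observation, not an algorithmic claim. Export:
GraphML (round-trippable with attributes) and TSV edge lists.

## Synthetic data: what it emulates, and what it does not

The generator produces every fixture class the pipeline needs, each with a
machine-checked manifest of planted truth:

* **SC strand fixtures** — toy chains (minimal backbones, 2 Å residue
  spacing) planting exactly one SC pair, a contact whose flanks are
  splayed so criterion 3 fails, a tight pair only 5 apart in sequence
  (criterion 1 failure), and a geometry whose best triplet selection
  yields exactly 6 of 9 contacts.
* **Toy connexons** — one or two rings of six chains spanning residues
  20–230, C6-symmetric, with the canonical Cys triads. An HC2 chain is the
  180°-rotation image of an HC1 chain about its radial axis, so the two
  rings are congruent by a proper rotation — as in a real gap junction —
  which is what makes template-based HC-HC assembly exact on these
  fixtures. Closed geometry puts canonical SG pairs at 2.05 Å; open
  geometry separates them to 4.4 Å and adds thiol hydrogens, with each
  subunit's 65C thiol aimed at its own 187C sulfur — one donor and one
  acceptor geometry per subunit, hence 12 Cys–Cys H-bonds across a
  dodecamer. Docked rings plant (56,195) as a trans-GJ SC on every subunit
  pair in both directions, and an opposing-58Q H-bond per docked pair.
  Residues with no planted role sit on a per-chain vertical line whose
  height tracks the residue number, so no unplanned long-range contact can
  arise.
* **Cylinder channels** — stacked atom rings with analytic inscribed
  radii, the pore oracle.
* **Probe micro-fixtures** — minimal two-residue geometries placing one
  candidate interaction at an exact distance, for cutoff boundary tests.

Trajectories are the base structure plus iid Gaussian positional jitter
(default σ 0.05 Å in tests), with scheduled interactions switched between
exact on/off geometries per frame and the per-frame truth recorded in the
manifest. This is explicitly **not** physical dynamics: there are no
correlated motions, no solvent, no thermodynamics, and the jitter is
uncorrelated across frames. Consequently, passing tests demonstrate that
the detectors, aggregators and profilers compute their geometric
definitions correctly and recover planted truth exactly — they do not
demonstrate anything about the conformational behaviour of real connexins,
for which the package must be run on real MD output. Generators self-verify
their manifests with the package detectors before returning; the test suite
keeps a separate brute-force oracle so the check is two-sided.

## Problem sizes and determinism

The bundled analyses run at desk scale: dodecamer fixtures of ≈10,000
atoms, trajectory fixtures of up to 10,000 frames at toy atom counts (the
production frame count, exercised for trajectory accounting), 2,000-frame
schedules for stability-fraction recovery, and 50 randomized fixtures for
oracle equivalence. Every stochastic component (jitter, schedules, pore
multi-starts) is seeded; the pipeline logs parameters, input hashes and
per-stage wall time, and identical configs with identical seeds produce
byte-identical outputs.

## Known limitations

* SC detection is purely geometric; energetic stabilization measures are
  out of scope, and agreement with any particular server implementation
  depends on its (unpublished) vdW table — the radii here are configurable
  for calibration.
* The trans-GJ H-bond list implements the stated donor/acceptor atoms
  verbatim, including the chemically unusual Asn OD1 donor (inert without
  an attached hydrogen).
* Pore profiles constrain sphere centres to planes normal to a fixed axis;
  strongly tilted or branched channels would need the full sphere-chain
  treatment.
* Multi-model semantics are "frames" only; NMR ensembles, insertion codes
  and altlocs beyond the first are out of scope.
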