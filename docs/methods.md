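# Methods

## The model

`dyncomm` detects *dynamic communities* — blocks of residues that move
cohesively — from a Gaussian Network Model (GNM) and quantifies how well
they agree with communities derived from molecular-dynamics (MD)
trajectories.

**GNM.** A protein is reduced to nodes (one C&alpha; per residue, or every
heavy atom for the mutant screen) joined by identical Hookean springs
whenever two nodes are within a cutoff distance r_c (contacts at exactly
r_c count as connected). The contact Kirchhoff matrix &Gamma; (graph
Laplacian: off-diagonal &minus;&gamma; for contacts, diagonal = contact
degree &times; &gamma;) encodes the network. The model assumes the input
structure is the energy minimum and that fluctuations about it are
isotropic Gaussians; their covariance is proportional to the pseudo-inverse
&Gamma;&#8315;&sup1; = &Sigma;&#7522; &lambda;&#7522;&#8315;&sup1;
V&#7522;V&#7522;&#7511; over the non-zero modes (a connected network has
exactly one zero mode, the uniform vector). The normalized cross-correlation
between nodes i and j is

    DCC_GNM(i,j) = Γ⁻¹(i,j) / √(Γ⁻¹(i,i) · Γ⁻¹(j,j))

computed over the lowest-frequency 5, 10, 20, 30 or 50 non-zero modes
(clipped with a warning for models with fewer than N&minus;1 &ge; 50
modes). The stiffness &gamma; cancels in the normalization, and because
&Gamma; depends only on inter-node distances, DCC is invariant to
rigid-body motion of the input coordinates.

**MD correlations.** For a C&alpha; trajectory, displacements about the
time mean give DCC_MD(i,j) = &lang;&Delta;r&#7522;&middot;&Delta;r&#11388;&rang; /
&radic;(&lang;|&Delta;r&#7522;|&sup2;&rang;&lang;|&Delta;r&#11388;|&sup2;&rang;),
with no mass weighting and no frame superposition. Unaligned trajectories
therefore conflate internal and rigid-body motion; callers who care should
superpose frames upstream. No equilibration trimming is applied.

**Communities.** Correlations are converted to dissimilarities
(1 &minus; DCC, range [0, 2]), clustered agglomeratively with WPGMA
(merged-cluster distance = plain average of the two children's distances),
and the dendrogram is cut into N_c = 2…10 communities by undoing the last
N_c &minus; 1 merges. Cutting by count rather than height makes the
partitions comparable across structures.

**Agreement metrics.**

* *Cohen's kappa*, K = (p_o &minus; p_e)/(1 &minus; p_e), between two
  partitions at each N_c, with Kappa_max = the best N_c (smallest on
  ties). Community labels from independent clusterings are arbitrary, so
  labels are first matched by maximizing the confusion-matrix trace
  (Hungarian assignment).
* *Closeness centrality* on the complete weighted network with edge
  weights 1 &minus; DCC: centrality(i) = 1/&Sigma;&#11388;
  shortest_path(i,j); the GNM and MD centrality profiles are compared by
  Pearson correlation (Spearman available).
* *RMSIP*, &radic;((1/n)&Sigma;&#7522;&Sigma;&#11388;(V&#7522;&middot;U&#11388;)&sup2;),
  between the n leading singular vectors of the two correlation matrices
  themselves (not of a trajectory covariance); n defaults to the GNM mode
  count.

**Mutant screen.** Mutant crystal structures are compared with a
wild-type using an all-heavy-atom GNM at r_c = 3.5 Å. The all-atom DCC
is reduced to residue level by extracting the C&alpha; rows/columns —
the least-assumption one-node-per-residue choice; per-residue-pair
averaging with re-normalization is available behind a flag. Residues are
matched between structures by (chain, residue number, insertion code)
intersection, and structures sharing under half of the wild-type's
residues are rejected. Each mutant is scored by kappa against the
wild-type communities per (mode subset, N_c), and medians are reported
per stability class. Classes in the packaged T4-lysozyme manifest come
from the published ΔΔG table verbatim — the two &minus;2.6 kcal/mol
mutants fall on opposite sides of the split, so a pure threshold cannot
reproduce it.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| r_c (C&alpha;) | 7.5 Å | contact cutoff for residue-level GNM |
| r_c (heavy atom) | 3.5 Å | contact cutoff for all-atom GNM |
| mode subsets | 5, 10, 20, 30, 50 | low-frequency modes used for DCC_GNM |
| N_c | 2–10 | community counts swept |
| &gamma; | 1 | spring stiffness (cancels in DCC) |
| zero_tol | 1e-10 &times; &lambda;_max | relative threshold separating the zero mode |

The cutoff grid {6, 6.5, 7, 7.5, 8} Å is accepted anywhere r_c is a
parameter, but no automatic selection criterion is implemented; 7.5 Å is
the fixed default.

## Numerical choices

* Dense `scipy.linalg.eigh` decomposition throughout; at the scale this
  package targets (up to a few thousand nodes, ~1300 heavy atoms for a
  small protein) this is fast and avoids iterative-solver tolerance
  questions.
* More than one numerically zero mode means a disconnected contact graph
  and is an error (raise r_c or extract the largest component) rather
  than a silent mode drop.
* WPGMA is implemented in-package with a documented tie rule: among
  minimal-distance cluster pairs, merge the pair whose (smallest leaf
  index, second smallest) is lexicographically least. Library
  implementations leave ties to internal ordering, which is not
  reproducible across versions. Merge heights match
  `scipy.cluster.hierarchy.linkage(method="weighted")` whenever distances
  are distinct. Non-monotone merge heights (possible because 1 &minus; DCC
  is not guaranteed ultrametric) are accepted with a logged warning.
* Community labels are canonical: community 1 contains the lowest node
  index, community 2 the lowest remaining index, and so on.
* Label alignment breaks ties among equal-trace assignments by minimizing
  the matched marginal products (the chance-agreement term p_e), which
  makes the aligned kappa invariant to label permutations of either input
  even when the optimal matching is degenerate.
* Shortest paths treat zero-weight edges (perfectly correlated pairs) as
  real edges; a node at distance zero from all others gets infinite
  centrality and a warning. Negative weights cannot arise from a valid
  correlation matrix and are clipped at zero with a warning.
* The trajectory correlation uses a two-pass chunked accumulation (means,
  then cross-products) so memory stays bounded in the number of nodes,
  identical to the naive formula to 1e-12.

## What the synthetic generators emulate

The bead-protein generator places each domain's beads on a compact cubic
lattice (3.8 Å spacing, the C&alpha; virtual bond length, with 0.3 Å
jitter) and separates consecutive domains by a 6.5 Å gap, inside the
7.5 Å cutoff, so the contact graph is connected but only facing beads
couple the domains. This reproduces the one property the community
pipeline needs — loosely coupled, internally cohesive spatial domains —
and nothing else: there is no backbone connectivity across domains, no
secondary structure, no side chains.

Trajectories are i.i.d. draws from the GNM's own Gaussian (per-axis
covariance amplitude &times; &Gamma;&#8315;&sup1;, amplitude 1 &asymp; 1 Å
RMS). By construction DCC_MD of such a trajectory converges to
DCC_GNM(all modes), which is what makes the MD-vs-GNM convergence tests
meaningful; it also means those tests validate the estimator and the
pipeline plumbing, **not** the physical claim that real MD correlations
resemble GNM correlations. That claim can only be tested on real
trajectories (the optional `scripts/t4_integration.py` harness covers the
mutant side when local PDB files are supplied; trajectory benchmarks
require external MD data and are out of scope here). Frames are
independent rather than time-correlated — the correlation estimator is a
pure time average and provably insensitive to frame order, so temporal
correlation would only slow convergence without changing the target.

Problem sizes in the shipped tests and in `scripts/acceptance.py` (20-bead
two-domain proteins, 20,000-frame trajectories, 12-node block matrices,
50 random models up to N = 30) were chosen as the smallest scales at which
the statistical contracts hold with comfortable margins; all run in
seconds.

## Known limitations

* No trajectory superposition, mass weighting or equilibration trimming;
  correlations from raw MD output include rigid-body components.
* mmCIF and binary trajectory formats (DCD/XTC) are not parsed; convert
  to multi-model PDB or a `frame,node,x,y,z` table first.
* Anisotropic network models, B-factor prediction, and automatic
  selection of the "true" community count are out of scope.
* Exact partition matches against other clustering tools are not
  guaranteed on real data when distances tie; only the documented tie
  rule is reproducible here.
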