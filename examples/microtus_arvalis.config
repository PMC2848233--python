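// Illustrative configuration: sex-specific demography of two common-vole
// (Microtus arvalis) lineages under a continent-island model.
//
// This fixture reproduces the published prior choices for that analysis.
// It is NOT runnable as-is: the genetic simulator and the summary-statistic
// calculator are external programs that are not bundled here (see the
// commented SIMULATOR lines).  Use it as a template for wiring abckit to a
// coalescent simulator.

// --- priors -------------------------------------------------------------
// island effective size (females), mean and sd of the island-size law
PRIOR N        uniform 10 500
PRIOR sigma_N  uniform 10 200
// ancestral population size, estimated on the log10 scale
PRIOR N_A      log10uniform 3 6.5
// male/female ratio of effective numbers
PRIOR beta     log10uniform -1 1
// female and male island-to-continent migration rates
PRIOR Nm       log10uniform -1.5 1
PRIOR Nm_males log10uniform -1.5 1
// divergence time of the two lineages, in generations
PRIOR T_DIV    uniform 40000 80000
// mitochondrial and mean microsatellite mutation rates
PRIOR mu_DNA   uniform 1e-8 5e-7
PRIOR mu_STR   uniform 1e-5 5e-4
// shape of the per-locus Gamma law of microsatellite rates (nuisance);
// per-locus rates are Gamma(alpha, rate = alpha / mu_STR), mean mu_STR
PRIOR alpha    uniform 8 12

// --- derived parameters handed to the simulator --------------------------
// mtDNA tracks females only; autosomal sizes count both sexes
RULE N_autosomal  2*(1+beta)*N
// autosomal gene flow combines female and male migrants
RULE Nm_autosomal 2*(Nm+Nm_males)

// --- sampler settings -----------------------------------------------------
SAMPLER     mcmc
CHAINLENGTH 1000000
DELTA       0.1
PHI         1
CALIBSIMS   10000

// --- external programs (placeholders, one call per marker type) -----------
// SIMULATOR simcoal2 mtdna.par.tmpl  mtdna.par  stats_mtdna.txt
// SIMULATOR simcoal2 microsat.par.tmpl microsat.par stats_microsat.txt
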