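# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Terrain, streams and barriers

The synthetic DEM is Gaussian-smoothed white noise (kernel width set by the
`roughness` parameter) rescaled to a 600 m relief with a mild north–south
tilt so the surface has a regional drainage direction.  Smoothed noise was
preferred over diamond-square synthesis because it is simpler and exactly
reproducible from a seed with no sequential state.

Stream derivation is the classic raster chain.  Pit filling uses
priority-flood with an epsilon increment (1e-6 m), which guarantees in one
pass that every non-border cell has a strictly descending path to the
border; D8 then picks, per cell, the neighbour maximising drop/distance
(diagonals count √2 × cell size), with exact ties resolved by a fixed
enumeration order (E, SE, S, SW, W, NW, N, NE) for determinism.  Flow
accumulation counts contributing cells in topological order; Strahler
ordering raises the order only where two or more inflows share the current
maximum.  The accumulation threshold that defines a stream cell defaults to
30 cells, chosen so that 64×64 synthetic terrains develop networks of
maximum order ≥ 3; it is a config parameter, not a law.

Strahler order ≥ 7 (i.e. "order > 6") makes a cell an absolute travel
barrier.  Because toy grids rarely reach order 7, the cutoff is exposed as
`barrier_order_min`; sweep-style tests use 3 so barriers actually occur.
Barriers apply in both seasons by default — the rule is stated without
seasonal qualification and wet-season flooding is the mechanism of interest
— and `barrier_seasons` can restrict it.  Whether a barrier severs a road
that crosses it (no bridges) is governed by `barrier_overrides_roads`,
default true; nothing in the source material resolves the bridge question,
so both behaviours are available.

## Cost surfaces and travel time

Roads are rasterised by supercover grid traversal: a cell is burned if the
polyline crosses its square footprint, not merely its centre, so diagonal
roads remain 8-connected.  Where classes collide the highest code (fastest
road) wins; roads always override land cover.  The class speed table is
shipped as `data/speed_table.csv` and hard-coded as the package default:
walking classes at 1–4 km/h (slower wet), local/provincial/national roads
at 10–60 km/h by mode and season, with local roads reverting to walking
pace in the bus scenarios.  One consequence worth knowing: wet-season buses
(40 km/h) outrun wet-season ambulances (25 km/h) on national roads, so
"bus is never better than car" holds only in the dry season.

Travel time is multi-source Dijkstra over the 8-connected cell graph
(scipy's sparse csgraph solver on a vectorised edge list; an independently
hand-coded heap Dijkstra serves as the test oracle).  Edge cost is
distance × mean of the two endpoint paces, the standard raster
cost-distance convention.  Facilities snap to the nearest traversable cell
within a Chebyshev radius of 3 cells (Euclidean tie-break, then row-major);
a facility walled in beyond that radius is an error naming the facility.
Unreachable cells get +∞ and classify as remote — people who cannot reach
care at all are remote by definition.  Travel-time zones are right-closed
intervals, so exactly 120 minutes falls in "90–120": remote means
*strictly* more than two hours.

## Population and remoteness

Both disaggregation methods conserve zone totals exactly (to 1e-6 relative,
verified at every stage) and keep populations real-valued; rounding to
whole persons would bias the proportion the index is built from.  Dwelling
points on cell edges belong to the south-east cell (half-open footprints),
making point-to-cell assignment single-valued.  A populated zone with no
infrastructure cells (or dwellings) is an error by default; a `uniform`
fallback spreads that zone over all its cells with a warning.  Zones with
zero population get an undefined (NaN) index and are excluded from the
regression.

## The mortality model

The generator draws deaths per zone-year as
Poisson(births · exp(β₀ + β_r·r + β_s·s)/100 000), capping draws at the
birth count (at realistic MMR the cap binds with negligible probability).
The fitter is hand-rolled IRLS with convergence at max|Δβ| < 1e-10 or 100
iterations, standard errors from the inverse Fisher information, dispersion
fixed at 1 (a quasi-Poisson flag rescales by the Pearson statistic).  MMR
is the mean of yearly ratios, not pooled deaths/births (pooling available
via flag); zero-birth zone-years are dropped with a warning.

The `mmr` mode regresses the ratio itself, which mirrors the two-row-per-
zone design directly but inherits a variance assumption (Var = μ on the
ratio scale) that is only exact when births × years ≈ 100 000 per zone;
`deaths_offset` is the statistically clean form and is the default oracle
in tests.  With equal births across rows the two modes give identical point
estimates.  Two-SD standardisation divides the centred remoteness index by
2·sd (n−1 denominator), putting its coefficient on the scale of a binary
covariate; binary covariates pass through untouched, and raw-scale
coefficients are recovered algebraically (β_std = β_raw·2·sd) and reported
alongside.

## Synthetic study region

Defaults describe a scaled-down rugged district: 64×64 cells of 250 m
(~16 km across — at walking speeds the two-hour threshold genuinely
partitions such a region), 32 administrative zones (the sub-district count
of the district the method was designed around), 5 towns joined by one
national spine with provincial branches and local feeders, 4 basic + 1
comprehensive EmOC facility on the major roads, 1 598 dwellings, female
fraction 0.5 and fertile-fraction 0.43.  Dwellings are exponential offsets
(scale 300 m) from random road positions plus a 10 % uniform background —
the background reflects the isolated dwellings that high-resolution mapping
finds far from roads, and ensures every zone can receive settlement cells
(generation retries up to 20 times otherwise, then fails loudly).  Zone
maps are nearest-seed partitions in cell space rather than true polygons:
the pipeline only ever consumes a zone raster.

What the generator does *not* emulate: real topographic correlation between
roads and terrain (synthetic roads are straight), land cover classified
from imagery, population gradients within zones beyond road proximity,
under-reporting of maternal deaths, and any spatial autocorrelation in
mortality beyond what remoteness induces.  Passing tests therefore
demonstrate correctness of the computational chain and recoverability of
the generating parameters, not calibration to any real district.

## Numerical and reproducibility choices

All generators and the pipeline are pure functions of their arguments
including the seed (numpy `default_rng`; stage seeds are fixed offsets from
the run seed).  Rasters serialise at %.17g so write→read round-trips are
bitwise exact, and reruns of a config produce byte-identical outputs (the
manifest stores SHA-256 checksums; its own runtimes differ between runs).
Problem sizes in the test-suite sweeps (40–64-cell grids, 50 landscapes,
200 oracle grids, 500 GLM replicates) were chosen as the smallest sizes at
which the compared quantities are stable.

## Known limitations

Isotropic travel only — no slope-dependent walking speed, no one-way or
time-varying roads; a single planar metric frame with no reprojection;
equal weighting of dwellings in the point method; Poisson/quasi-Poisson
variance only (no mixed effects or spatial error terms); the remoteness
index ignores every non-geographic barrier to care, which is precisely the
gap the surrounding research programme documents.
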