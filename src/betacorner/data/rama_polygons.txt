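# Allowed-region polygons for Ramachandran classification.
# Format: one vertex per line: <category> <polygon-name> <phi> <psi>
# Categories: general, glycine, pre-proline, proline.
# Polygons are closed implicitly (last vertex joins the first).  Outer edges
# extend slightly past +/-180 so that points on the wrap seam fall inside.
# These are coarse, contour-style allowed regions; they are a configuration
# file, not a fitted density, and may be edited.

general beta -185 45
general beta -45 45
general beta -45 185
general beta -185 185

general beta_wrap -185 -185
general beta_wrap -45 -185
general beta_wrap -45 -155
general beta_wrap -185 -155

general alpha -160 -80
general alpha -20 -80
general alpha -20 45
general alpha -160 45

general left_alpha 40 0
general left_alpha 100 0
general left_alpha 100 90
general left_alpha 40 90

# glycine: the general regions plus their point reflections (phi,psi) ->
# (-phi,-psi); glycine has no side chain and its map is centro-symmetric.
glycine beta -185 45
glycine beta -45 45
glycine beta -45 185
glycine beta -185 185

glycine beta_wrap -185 -185
glycine beta_wrap -45 -185
glycine beta_wrap -45 -155
glycine beta_wrap -185 -155

glycine alpha -160 -80
glycine alpha -20 -80
glycine alpha -20 45
glycine alpha -160 45

glycine left_alpha 40 0
glycine left_alpha 100 0
glycine left_alpha 100 90
glycine left_alpha 40 90

glycine beta_inv 185 -45
glycine beta_inv 45 -45
glycine beta_inv 45 -185
glycine beta_inv 185 -185

glycine beta_wrap_inv 185 185
glycine beta_wrap_inv 45 185
glycine beta_wrap_inv 45 155
glycine beta_wrap_inv 185 155

glycine alpha_inv 160 80
glycine alpha_inv 20 80
glycine alpha_inv 20 -45
glycine alpha_inv 160 -45

glycine left_alpha_inv -40 0
glycine left_alpha_inv -100 0
glycine left_alpha_inv -100 -90
glycine left_alpha_inv -40 -90

# pre-proline: beta as general, alpha narrowed (steric clash with the
# following proline ring).
pre-proline beta -185 45
pre-proline beta -45 45
pre-proline beta -45 185
pre-proline beta -185 185

pre-proline beta_wrap -185 -185
pre-proline beta_wrap -45 -185
pre-proline beta_wrap -45 -155
pre-proline beta_wrap -185 -155

pre-proline alpha -140 -60
pre-proline alpha -40 -60
pre-proline alpha -40 10
pre-proline alpha -140 10

pre-proline left_alpha 40 20
pre-proline left_alpha 100 20
pre-proline left_alpha 100 100
pre-proline left_alpha 40 100

# proline: phi pinned near -65 by the ring.
proline beta -110 60
proline beta -40 60
proline beta -40 185
proline beta -110 185

proline beta_wrap -110 -185
proline beta_wrap -40 -185
proline beta_wrap -40 -155
proline beta_wrap -110 -155

proline alpha -110 -70
proline alpha -40 -70
proline alpha -40 10
proline alpha -110 10
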