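"""Structural analysis of a constructed mixed micelle.

Builds a frame with a planted 41-molecule micelle (28 SDS + 13 cholate),
free cholate monomers and a known condensed/free Na+ split, then runs the
structural analyses: cluster recovery, shape anisotropy, radial bead
distribution and the SDS orientation angle.
"""

import numpy as np

from micellemix.cgmodel import Trajectory, Frame
from micellemix.cluster import find_clusters
from micellemix.ions import classify_ions
from micellemix.shape import (
    gyration_anisotropy,
    orientation_angles,
    radial_profile,
    unwrap_cluster,
)
from micellemix.synth import ClusterSpec, ConfigSpec, build_configuration

spec = ConfigSpec(clusters=(ClusterSpec(28, 13),), free_ca=17, free_sds=2,
                  planted_condensed=6, box=220.0, seed=3)
frame, truth = build_configuration(spec)

asg = find_clusters(frame)
big = int(np.argmax(asg.sizes))
print(f"clusters found      : {asg.n_clusters} "
      f"(planted {len(truth.sizes)})")
print(f"largest cluster     : {asg.sizes[big]} molecules, "
      f"SDS fraction {asg.sds_fraction[big]:.3f} (28/41 = {28 / 41:.3f})")

coords, _ = unwrap_cluster(frame, asg, big)
g = gyration_anisotropy(coords)
print(f"shape anisotropy K2 : {g.k2:.3f} "
      f"(0 = spherical, 1 = linear; Rg = {g.radius_of_gyration:.1f} A)")

part = classify_ions(frame)
print(f"Na+ partition       : {part.n_condensed} condensed / "
      f"{part.n_free} free (planted 6/54)")

traj = Trajectory([Frame(frame.topology, frame.positions, frame.box,
                         time_us=1.0)])
rp = radial_profile(traj, "SDS", "SO3", window=(0.5, 1.5),
                    min_cluster_size=20)
print(f"SO3 radial peak     : {rp.peak_r:.1f} A from the micelle COM")

ap = orientation_angles(traj, window=(0.5, 1.5), min_cluster_size=20)
print(f"SDS orientation     : mean Theta = {ap.angles.mean():.0f} deg over "
      f"{ap.n_molecules} molecules")
print()
print("The planted composition, ion split and geometry are recovered")
print("exactly; on random blob micelles the orientation is isotropic")
print("(Theta ~ 90 deg), unlike the inward-pointing tails of a real micelle.")
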