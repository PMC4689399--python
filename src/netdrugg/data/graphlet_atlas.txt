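# graphlet atlas: 30 graphlets on 2-5 nodes, 73 node orbits
# graphlet <id> nodes=<k> edges=<edge list> orbits=<orbit id per node>
graphlet G0 nodes=2 edges=[0-1] orbits=[0 0]
graphlet G1 nodes=3 edges=[0-1 1-2] orbits=[1 2 1]
graphlet G2 nodes=3 edges=[0-1 1-2 0-2] orbits=[3 3 3]
graphlet G3 nodes=4 edges=[0-1 1-2 2-3] orbits=[4 5 5 4]
graphlet G4 nodes=4 edges=[0-1 0-2 0-3] orbits=[7 6 6 6]
graphlet G5 nodes=4 edges=[0-1 1-2 2-3 3-0] orbits=[8 8 8 8]
graphlet G6 nodes=4 edges=[0-1 1-2 0-2 0-3] orbits=[11 10 10 9]
graphlet G7 nodes=4 edges=[0-1 0-2 0-3 1-2 1-3] orbits=[13 13 12 12]
graphlet G8 nodes=4 edges=[0-1 0-2 0-3 1-2 1-3 2-3] orbits=[14 14 14 14]
graphlet G9 nodes=5 edges=[0-1 1-2 2-3 3-4] orbits=[15 16 17 16 15]
graphlet G10 nodes=5 edges=[0-1 1-2 2-3 1-4] orbits=[19 21 20 18 19]
graphlet G11 nodes=5 edges=[0-1 0-2 0-3 0-4] orbits=[23 22 22 22 22]
graphlet G12 nodes=5 edges=[0-1 0-2 1-2 0-3 0-4] orbits=[26 25 25 24 24]
graphlet G13 nodes=5 edges=[0-1 0-2 1-2 2-3 3-4] orbits=[29 29 30 28 27]
graphlet G14 nodes=5 edges=[0-1 0-2 1-2 0-3 1-4] orbits=[33 33 32 31 31]
graphlet G15 nodes=5 edges=[0-1 1-2 2-3 3-4 4-0] orbits=[34 34 34 34 34]
graphlet G16 nodes=5 edges=[0-1 1-2 2-3 3-0 0-4] orbits=[38 37 36 37 35]
graphlet G17 nodes=5 edges=[0-1 0-2 0-3 1-2 1-3 2-4] orbits=[42 42 41 40 39]
graphlet G18 nodes=5 edges=[0-1 0-2 1-2 0-3 0-4 3-4] orbits=[44 43 43 43 43]
graphlet G19 nodes=5 edges=[0-1 0-2 0-3 1-2 1-3 0-4] orbits=[48 47 46 46 45]
graphlet G20 nodes=5 edges=[0-2 0-3 0-4 1-2 1-3 1-4] orbits=[50 50 49 49 49]
graphlet G21 nodes=5 edges=[1-2 2-3 3-4 4-1 0-1 0-2] orbits=[52 53 53 51 51]
graphlet G22 nodes=5 edges=[0-2 0-3 0-4 1-2 1-3 1-4 0-1] orbits=[55 55 54 54 54]
graphlet G23 nodes=5 edges=[0-2 0-3 0-4 1-2 1-3 1-4 2-3] orbits=[57 57 58 58 56]
graphlet G24 nodes=5 edges=[1-2 2-3 3-4 0-1 0-2 0-3 0-4] orbits=[61 59 60 60 59]
graphlet G25 nodes=5 edges=[0-1 0-2 0-3 1-2 1-3 2-3 0-4] orbits=[64 63 63 63 62]
graphlet G26 nodes=5 edges=[0-3 0-4 1-2 1-3 1-4 2-3 2-4 3-4] orbits=[65 66 66 67 67]
graphlet G27 nodes=5 edges=[0-2 0-3 0-4 1-2 1-3 1-4 2-4 3-4] orbits=[68 68 68 68 69]
graphlet G28 nodes=5 edges=[0-2 0-3 0-4 1-2 1-3 1-4 2-3 2-4 3-4] orbits=[70 70 71 71 71]
graphlet G29 nodes=5 edges=[0-1 0-2 0-3 0-4 1-2 1-3 1-4 2-3 2-4 3-4] orbits=[72 72 72 72 72]
# orbit <id> graphlet=<parent> multiplicity=<nodes at orbit>
orbit 0 graphlet=G0 multiplicity=2
orbit 1 graphlet=G1 multiplicity=2
orbit 2 graphlet=G1 multiplicity=1
orbit 3 graphlet=G2 multiplicity=3
orbit 4 graphlet=G3 multiplicity=2
orbit 5 graphlet=G3 multiplicity=2
orbit 6 graphlet=G4 multiplicity=3
orbit 7 graphlet=G4 multiplicity=1
orbit 8 graphlet=G5 multiplicity=4
orbit 9 graphlet=G6 multiplicity=1
orbit 10 graphlet=G6 multiplicity=2
orbit 11 graphlet=G6 multiplicity=1
orbit 12 graphlet=G7 multiplicity=2
orbit 13 graphlet=G7 multiplicity=2
orbit 14 graphlet=G8 multiplicity=4
orbit 15 graphlet=G9 multiplicity=2
orbit 16 graphlet=G9 multiplicity=2
orbit 17 graphlet=G9 multiplicity=1
orbit 18 graphlet=G10 multiplicity=1
orbit 19 graphlet=G10 multiplicity=2
orbit 20 graphlet=G10 multiplicity=1
orbit 21 graphlet=G10 multiplicity=1
orbit 22 graphlet=G11 multiplicity=4
orbit 23 graphlet=G11 multiplicity=1
orbit 24 graphlet=G12 multiplicity=2
orbit 25 graphlet=G12 multiplicity=2
orbit 26 graphlet=G12 multiplicity=1
orbit 27 graphlet=G13 multiplicity=1
orbit 28 graphlet=G13 multiplicity=1
orbit 29 graphlet=G13 multiplicity=2
orbit 30 graphlet=G13 multiplicity=1
orbit 31 graphlet=G14 multiplicity=2
orbit 32 graphlet=G14 multiplicity=1
orbit 33 graphlet=G14 multiplicity=2
orbit 34 graphlet=G15 multiplicity=5
orbit 35 graphlet=G16 multiplicity=1
orbit 36 graphlet=G16 multiplicity=1
orbit 37 graphlet=G16 multiplicity=2
orbit 38 graphlet=G16 multiplicity=1
orbit 39 graphlet=G17 multiplicity=1
orbit 40 graphlet=G17 multiplicity=1
orbit 41 graphlet=G17 multiplicity=1
orbit 42 graphlet=G17 multiplicity=2
orbit 43 graphlet=G18 multiplicity=4
orbit 44 graphlet=G18 multiplicity=1
orbit 45 graphlet=G19 multiplicity=1
orbit 46 graphlet=G19 multiplicity=2
orbit 47 graphlet=G19 multiplicity=1
orbit 48 graphlet=G19 multiplicity=1
orbit 49 graphlet=G20 multiplicity=3
orbit 50 graphlet=G20 multiplicity=2
orbit 51 graphlet=G21 multiplicity=2
orbit 52 graphlet=G21 multiplicity=1
orbit 53 graphlet=G21 multiplicity=2
orbit 54 graphlet=G22 multiplicity=3
orbit 55 graphlet=G22 multiplicity=2
orbit 56 graphlet=G23 multiplicity=1
orbit 57 graphlet=G23 multiplicity=2
orbit 58 graphlet=G23 multiplicity=2
orbit 59 graphlet=G24 multiplicity=2
orbit 60 graphlet=G24 multiplicity=2
orbit 61 graphlet=G24 multiplicity=1
orbit 62 graphlet=G25 multiplicity=1
orbit 63 graphlet=G25 multiplicity=3
orbit 64 graphlet=G25 multiplicity=1
orbit 65 graphlet=G26 multiplicity=1
orbit 66 graphlet=G26 multiplicity=2
orbit 67 graphlet=G26 multiplicity=2
orbit 68 graphlet=G27 multiplicity=4
orbit 69 graphlet=G27 multiplicity=1
orbit 70 graphlet=G28 multiplicity=2
orbit 71 graphlet=G28 multiplicity=3
orbit 72 graphlet=G29 multiplicity=5
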