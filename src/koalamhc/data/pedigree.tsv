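family_id	joey	dam	sire
1	Angelica	Jazz	Barney
2	Myrtle	Rusa	Keeley
3	Kia	Jubilee	Byron
4	Sargent	Elata	Byron
5	Milton	Sinammon	Fingal
6	Tully	Minx	Byron
7	Jester	Halle	Keeley
8	Esmeralda	Kirra	Strudel
9	Feenie	Dama	Strudel
10	Nat	Victory	Aster
11	Davis	Rookie	Strudel
12	Drew	Rookie	Barney
13	Urchin	Guppy	Yeti
14	Hamlet	Zap	Byron
15	Merlin	Kirra	Yeti
16	Waffle	Crumble	Wisely
17	Cordelia	Zap	Byron
18	Archer	Minx	O'Malley
19	Major	Elata	
20	Barney	Minx	
21	Sprocket	Dama	
22	Clifton	Mooloolah	
23	Byron	Mooloolah	
24	Daiquiri	Liana	
25	Virginea	Elata	
26	Jervis	Mooloolah	
27	Aster	Rusa	
28	Fraggle	Dama	
29	Fingal	Mooloolah	
30	Pellita	Elata	
31	Kirra	Mooloolah	
32	Bkley	Rusa	
33	Tango		Byron
34	Hermit		Rory
35	Ficus		Orinoco
36	Claret		Fingal
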