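family_id	relationship	name	UA	UC	DAB	DBB	DCB	DMB
1	dam	Jazz	08:01;10:01;11:01	01:01	10;15;19;21	02;05	01;03	02
1	sire	Barney	08:01;11:01	01:03	10;15;19;21	02;05	01	01
1	joey	Angelica	08:01;10:01;11:01	01:01;01:03	10;15;19;21	02;05	01	01;02
2	dam	Rusa	08:01;09:01;11:01	01:01	15;19;21	02;04	01;02	02;03
2	sire	Keeley	08:01;09:01	05:01	15;19;21	02;04	01;02	02;04
2	joey	Myrtle	08:01;09:01;11:01	02:01	15;19;21	04	01;02	02;03
3	dam	Jubilee	08:01;09:01;11:01	01:01;05:01	10;19;21;30	01;03;04	01;03	02;03
3	sire	Byron	10:01;13:01	01:01;05:02	15;19;21	01;02	01	02;03
3	joey	Kia	08:01;10:01;11:01	01:01	15;19;21;30	02;03	01	02;03
4	dam	Elata	01:01	01:01	10;19;21	02;04;05;09	03	01;02
4	sire	Byron	10:01;13:01	01:01;05:02	15;19;21	01;02	01	02;03
4	joey	Sargent	01:01;13:01	05:02	10;15;19;21	01;04	01;03	02;03
5	dam	Sinammon	08:01;10:01;11:01	05:02	10;15;19;21	01	01	03
5	sire	Fingal	08:01;11:01;13:01	01:01	10;15;19;21	02;03;05	01	01;04
5	joey	Milton	08:01;10:01;13:01	01:01;05:02	10;19;21	01;03	01	01;03
6	dam	Minx	08:01;11:01	05:02	15;19;21;22;24;39	04;06;07	01	01;02
6	sire	Byron	10:01;13:01	01:01;05:02	15;19;21	01;02	01	02;03
6	joey	Tully	08:01;10:01;11:01	05:02	15;19;21	01;06;07	01	02;03
7	dam	Halle	01:01;10:01	01:01	15;19;21	02;05	01;03	02
7	sire	Keeley	08:01;09:01	05:01	15;19;21	02;04	01;02	02;04
7	joey	Jester	01:01;08:01;09:01	01:01;05:01	15;19;21	02;05	02;03	02;04
8	dam	Kirra	08:01;09:01;13:01	01:01	10;15;19;21	02;03	01	01;02
8	sire	Strudel	01:01;12:01	01:01;01:03	10;19;21;23	02;03	01	01
8	joey	Esmeralda	12:01;13:01	01:01	15;19;21;23	02;03;04	01	01;02
9	dam	Dama	08:01;11:01	01:03	10;15;19;21	02;05	01	01
9	sire	Strudel	01:01;12:01	01:01;01:03	10;19;21;23	02;03	01	01
9	joey	Feenie	08:01;11:01;12:01	01:03	15;19;21;23	02;05	01	01
10	dam	Victory	08:01;11:01;12:01	01:01;05:01	15;19;21;30	02;06;07	01	02;04
10	sire	Aster	08:01;10:01;11:01	01:01	15;19;21;23	02;04	01;02	03;04
10	joey	Nat	08:01;11:01	01:01	15;19;21	02;04	01;02	02;03
11	dam	Rookie	08:01;09:01;12:01	01:01	10;15;19;21	02;04;05	02;03	01;03
11	sire	Strudel	01:01;12:01	01:01;01:03	10;19;21;23	02;03	01	01
11	joey	Davis	01:01;08:01;09:01	01:01;01:03	10;15;19;21	02;03;04;05	01;02	01;03
12	dam	Rookie	08:01;09:01;12:01	01:01	10;15;19;21	02;04;05	02;03	01;03
12	sire	Barney	08:01;11:01	01:03	10;15;19;21	02;05	01	01
12	joey	Drew	08:01;11:01;12:01	01:01	10;19;21;22;24;39	02;04;05	01;03	01
13	dam	Guppy	08:01;09:01;10:01	01:01	10;19;21;22;24;39	02;04	01;03	01;02
13	sire	Yeti	01:01;08:01;11:01	01:01	15;19;21;23	01;03	01	01;02
13	joey	Urchin	01:01;08:01;09:01	01:01	10;19;21;23	03;04	01	01
14	dam	Zap	01:01;10:01	01:01	10;15;19;21	02;05	01;03	02;03
14	sire	Byron	10:01;13:01	01:01;05:02	15;19;21	01;02	01	02;03
14	joey	Hamlet	10:01;13:01	01:01	15;19;21	02;05	01;03	02
15	dam	Kirra	08:01;09:01;13:01	01:01	10;15;19;21	02;03	01	01;02
15	sire	Yeti	01:01;08:01;11:01	01:01	15;19;21;23	01;03	01	01;02
15	joey	Merlin	08:01;09:01;11:01	01:01	10;15;19;21	01;03	01	01;02
16	dam	Crumble	10:01;12:01	05:01	10;19;21	04;06;07	01;03	01;04
16	sire	Wisely	01:01;12:01	01:01;01:03	15;19;21	02;05	01	02
16	joey	Waffle	01:01;10:01	01:01;05:01	10;15;18;19;21	02;06;07	01	02;04
17	dam	Zap	01:01;10:01	01:01	10;15;19;21	02;05	01;03	02;03
17	sire	Byron	10:01;13:01	01:01;05:02	15;19;21	01;02	01	02;03
17	joey	Cordelia	10:01	01:01	15;19;21	02	01;03	02
18	dam	Minx	08:01;11:01	05:02	15;19;21;22;24;39	04;06;07	01	01;02
18	sire	O'Malley	08:01;10:01;11:01	01:01;05:02	15;19;21;30	01;03	01	03
18	joey	Archer	08:01;10:01;11:01	01:01;05:02	15;19;21;30	03;06;07	01	02;03
19	dam	Elata	01:01	01:01	10;19;21	02;04;05;09	03	01;02
19	joey	Major	01:01;08:01;11:01	01:01	10;19;21;30	03;04	01;03	02;03
20	dam	Minx	08:01;11:01	05:02	15;19;21;22;24;39	04;06;07	01	01;02
20	joey	Barney	08:01;11:01	01:03	10;15;19;21	02;05	01	01
21	dam	Dama	08:01;11:01	01:03	10;15;19;21	02;05	01	01
21	joey	Sprocket	08:01;09:01;11:01	01:01;01:03	10;15;19;21	02;03;05	01	01;02
22	dam	Mooloolah	08:01;11:01;13:01	01:01	10;15;19;21	02;03	01	01;02
22	joey	Clifton	08:01;09:01;13:01	01:01;05:02	10;15;19;21	01;02	01	02;03
23	dam	Mooloolah	08:01;11:01;13:01	01:01	10;15;19;21	02;03	01	01;02
23	joey	Byron	10:01;13:01	01:01;05:02	15;19;21	01;02	01	02;03
24	dam	Liana	10:01;12:01	01:01;01:03	21;23	02;03;05	01	01;02
24	joey	Daiquiri	08:01;09:01;10:01	01:01	15;19;21;23	03	01;03	01;02
25	dam	Elata	01:01	01:01	10;19;21	02;04;05;09	03	01;02
25	joey	Virginea	01:01;10:01	02:01	10;15;19;21	04	02;03	02;03
26	dam	Mooloolah	08:01;11:01;13:01	01:01	10;15;19;21	02;03	01	01;02
26	joey	Jervis	08:01;11:01;13:01	01:01	10;19;21;30	03;04	01	01
27	dam	Rusa	08:01;09:01;11:01	01:01	15;19;21	02;04	01;02	02;03
27	joey	Aster	08:01;10:01;11:01	01:01	15;19;21;23	02;04	01;02	03;04
28	dam	Dama	08:01;11:01	01:03	10;15;19;21	02;05	01	01
28	joey	Fraggle	01:01;08:01;11:01	01:01;01:03	10;15;19;21	01;02;05	01	01;02
29	dam	Mooloolah	08:01;11:01;13:01	01:01	10;15;19;21	02;03	01	01;02
29	joey	Fingal	08:01;11:01;13:01	01:01	10;15;19;21	02;03;05	01	01;04
30	dam	Elata	01:01	01:01	10;19;21	02;04;05;09	03	01;02
30	joey	Pellita	01:01;12:01	01:01	10;19;21;23	03;04	01;03	01;02
31	dam	Mooloolah	08:01;11:01;13:01	01:01	10;15;19;21	02;03	01	01;02
31	joey	Kirra	08:01;09:01;13:01	01:01	10;15;19;21	02;03	01	01;02
32	dam	Rusa	08:01;09:01;11:01	01:01	15;19;21	02;04	01;02	02;03
32	joey	Bkley	08:01;09:01;11:01	01:01	15;19;21	03;04	01;02	01;03
33	sire	Byron	10:01;13:01	01:01;05:02	15;19;21	01;02	01	02;03
33	joey	Tango	08:01;10:01;11:01	01:01	10;15;19;21	02	01	02
34	sire	Rory	10:01	02:01	10;19;21;22;24;39	04	01;03	01;02
34	joey	Hermit	08:01;10:01;11:01	02:01	10;19;21	04	03	01;02
35	sire	Orinoco	08:01;10:01;11:01	01:01;05:02	15;19;21	01;02	01	03
35	joey	Ficus	08:01;10:01;11:01	01:01;05:02	15;19;21	01;02	01	02;03
36	sire	Fingal	08:01;11:01;13:01	01:01	10;15;19;21	02;03;05	01	01;04
36	joey	Claret	08:01;11:01;13:01	01:01	15;19;21;23	02;04;05	01;03	02;04
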