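id,artist,title,label,year,tempo_bpm
1,Epica,Illusive Consensus,Transmission,2003,132
2,Gregory Porter,On My Way to Harlem (Radio Edit),Motema,2012,138
3,Interpol,Slow Hands,Matador,2004,139
4,The Supremes,I Hear a Symphony,Motown,1965,139
5,Van Halen,Ain’t Talkin’ ‘Bout Love,Warner Bros,1978,139
6,Combichrist,Electrohead,Out of Line/Metropolis,2007,140
7,dEUS,The Soft Fall,PIAS,2012,140
8,P!nk,Who Knew,LaFace,2006,140
9,Noisettes,Never Forget You,Mercury/Vertigo,2009,141
10,Rammstein,Benzin,Motor,2005,142
11,Royksopp,Tricky Tricky,Astralwerk/EMI,2009,142
12,Deftones,My Own Summer (Shove It),Maverick/Warner Bros,1997,143
13,16 Horsepower,Outlaw Song,Jetset,2006,144
14,Coldplay,In My Place,Parlophone,2002,144
15,The Hickey Underworld,Future Words,PIAS,2009,145
16,ABBA,Waterloo (English Version),Polar/Epic,1973,146
17,Steppenwolf,Born to Be Wild,Dunhill/RCA,1967,146
18,The Sisters of Mercy,Alice,Merciful Release,1982,146
19,School Is Cool,The World Is Gonna End Tonight,Not on label,2011,147
20,Tom Odell,I Know,Columbia/In the Name Of,2012,147
21,Trixie Whitley,Irene,Unday Records,2013,147
22,Aphex Twin,Flim,Warp/Sire/WEA,1997,148
23,Bruce Springsteen,Dancing In the Dark,Columbia,1984,148
24,Nneka,Heartbeat,Yo Mama’s Recording,2008,148
25,Alt-J,Breezeblocks,Infectious,2012,149
26,Marco Borsato,Ik leef niet meer voor jou,Polydor,1995,149
27,A Perfect Circle,Thinking of You,Virgin,2000,150
28,Editors,An End Has a Start,Kitchenware/FADER,2007,150
29,Florence and The Machine,Dog Days Are Over,Island,2009,150
30,Guns N’ Roses,It’s So Easy,Geffen Records/Interscope,1987,150
31,Katy Perry,E.T.,Capitol,2010,150
32,Pearl Jam,Lightning Bolt,Monkeywrench/Republic,2013,151
33,The Killers,Spaceman,Island/Vertigo,2008,151
34,Bloc Party,Flux,Wichita/Vice,2007,152
35,Elton John,Saturday Night’s Alright (For Fighting),MCA/DJM,1973,152
36,P!nk,Are We All We Are,RCA,2012,152
37,De Staat,Sweatshop,Cool Green Recordings,2011,153
38,Ike & Tina Turner,Nutbush City Limits,United Artists,1973,153
39,Kings of Leon,Sex On Fire,RCA,2008,153
40,OutKast,B.O.B.,LaFace/Arista,2000,153
41,The Black Eyed Peas,Pump It,Interscope,2005,153
42,Massive Attack,Teardrop,Circa/Virgin,1998,154
43,Kaiser Chiefs,Never Miss a Beat,B-Unique/Universal,2008,155
44,Morphine,Honey White,Rykodisc,1995,155
45,The Pipettes,Your Kisses Are Wasted On Me,Memphis Industries/Cherrytree,2006,155
46,The Strokes,Juicebox,RCA,2006,155
47,Hooverphonic,Mad About You (Orchestra Version),Columbia,2012,156
48,Nirvana,In Bloom,DGC,1991,156
49,The Van Jets,Ricochet,Belvédère,2005,156
50,Air,Surfing On a Rocket,Virgin,2004,157
51,Millencolin,No Cigar,Epitaph,2000,157
52,The Beach Boys,Surfin’ USA,Capitol,1963,157
53,Shaggy,Boombastic,Virgin,1995,158
54,Jones & Stephenson,The First Rebirth (Original Mix),Prolekult,1994,159
55,Kings of Leon,California Waiting,RCA/HandMeDown,2003,159
56,Michael Sembello,Maniac,Warner Bros,1983,159
57,OutKast,Hey Ya! (Radio Mix Club Mix),LaFace,2003,159
58,Beyonce,Halo,Columbia,2008,160
59,Birdman & Lil Wayne,Stuntin’ Like My Daddy (Street),Cash Money/Universal,2006,160
60,Customs,Justine,Noisesome/EMI,2009,160
61,Mastodon,Spectrelight,Reprise/Roadrunner,2011,160
62,TNGHT,Higher Ground,Warp/LuckyMe,2012,160
63,P.O.D.,Alive,Atlantic,2001,161
64,Queens of the Stone Age,Little Sister,Interscope,2005,161
65,‘T Hof Van Commerce,Baes (Radio Edit),Plasticine,2012,162
66,Black Sabbath,Paranoid,Vertigo,1970,162
67,Blondie,One Way or Another,Chrysalis,1978,162
68,Karate,Ice or Ground,Southern,2002,162
69,Moby,Feeling So Real,Mute/Elektra,1995,162
70,Orchestral Manoeuvres In the Dark,Electricity,Factory,1979,162
71,U96,Love Religion (Video Edit),Guppy/Motor,1995,162
72,Wham!,Wake Me Up Before You GoGo,Columbia,1984,162
73,Bomfunk MC’s,Freestyler,Sony Music Finland/Epidrome,1999,163
74,Jamaica,Cross the Fader,Downtown,2011,164
75,Midlake,Antiphon,Bella Union,2013,164
76,Muse,Survival,Helium 3/Warner Music Group,2012,164
77,Sugababes,About You Now,Island,2007,164
78,Ella Fitzgerald,"A-Tisket, A-Tasket",Golden Options,2008,165
79,Ike & Tina Turner,River Deep Mountain High,Philes,1966,165
80,Green Day,Boulevard of Broken Dreams,Reprise,2004,166
81,Pixies,Where Is My Mind,4 AD,1988,166
82,Rammstein,Mann gegen Mann,Universal,2005,166
83,Arctic Monkeys,Do I Wanna Know,Domino,2013,170
84,Chet Faker,I’m Into You,Opulent/Remote Control,2012,170
85,Joy Division,Disorder,Factory,1979,170
86,Panic! At the Disco,I Write Sins Not Tragedies,Fueled by Ramen/Decaydance,2005,170
87,Queens of the Stone Age,No One Knows,Interscope,2002,170
88,The All-American Rejects,My Paper Heart,Doghouse/DreamWorks,2002,170
89,Foo Fighters,The Pretender,Roswell/RCA,2007,172
90,Netsky,Love Has Gone,Hospital,2012,172
91,Paramore,Misery Business,Fueled by Ramen,2007,172
92,The Streets,Fit But You Know It,Locked On/679,2004,172
93,DJ Fresh,Hot Right Now (Radio Edit),Ministry of Sound,2012,174
94,Interpol,A Time To Be So Small,Matador,2004,174
95,Kanye West,Homecoming (feat. Chris Martin),Roc-A-Fella/Def Jam,2008,174
96,Rudimental,Waiting All Night (feat. Ella Eyre),Asylum,2013,174
97,Kelis & Andre 3000,Millionaire,Virgin,2004,176
98,Technohead,I Wanna Be a Hippy,Mokum,1995,177
99,Komatsu,Comin’,Lighttown Fidelity,2011,178
100,Mo’ Horizons,Pe Na Estrada (Radio Edit),Agogo,2008,178
101,Tony Bennett & Lady Gaga,The Lady Is a Tramp,Sony Music Entertainment,2011,179
102,One Direction,Kiss You,Syco/Columbia,2012,180
103,Red Hot Chili Peppers,Can’t Stop,Warner Music,2002,182
104,The Pointer Sisters,I’m So Excited,Planet,1982,184
105,Ok Go,Don’t Ask Me,Capitol,2002,186
106,Joan Jett & The Blackhearts,I Love Rock ‘N Roll,RAK,1975,188
107,Wheatus,Teenage Dirtbag,Columbia,2000,188
108,Absynthe Minded,Pretty Horny Flow,Abeille Musique,2008,190
109,Eminem,Berzerk,Aftermath Entertainment/Shady/Interscope,2013,190
110,Macklemore & Ryan Lewis,Thrift Shop (feat. Wanz),Macklemore LLC/ADA,2012,190
111,Roxette,The Look,EMI,1988,190
112,Isbells,As Long As It Takes,Zeal,2009,197
113,Beyonce,Crazy In Love (feat. Jay-Z),Columbia/Music World,2003,198
114,Rihanna,Pon de Replay,Def Jam,2005,198
115,Gorillaz,Stylo (Radio Edit) [feat. Mos Def & Bobby Womack],Parlophone/Virgin,2010,200
116,Wallace Vanborn,Atom Juggler,PIAS,2010,200
117,Linkin Park,In the End,Warner Bros,2000,210
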