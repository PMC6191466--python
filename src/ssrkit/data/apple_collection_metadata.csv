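accession_id,name,collection,status,ploidy
001,Cerina,c01,LV,D
002,Zuccherina,c01,LV,D
003,Gelato Cola,c01,LV,D
004,Ghiacciola,c01,LV,P
005,Pom de L'oio Rosso,c01,LV,D
006,'E Santu Giuanni,c01,LV,D
007,'E Santu Giuanni Rossa,c01,LV,D
008,Roggia,c01,LV,D
009,Ruzine,c01,LV,D
010,Ruzza,c01,LV,D
011,Sona,c01,LV,D
012,Ruzza,c02,LV,D
013,San Giovanni,c02,LV,D
014,Oleosa,c02,LV,D
015,A Sonagli,c02,LV,D
016,Gelata,c02,LV,D
017,Cera,c02,LV,D
018,Roggia,c03,LV,D
019,Gris d'la composta,c04,LV,D
020,Gris canavoeit,c04,LV,D
021,San Sebastian,c04,LV,P
022,Ruggine piatta,c04,LV,D
023,Buras,c04,LV,P
024,Grigia di Torriana,c04,LV,D
025,Oliata,c05,LV,P
026,Diacciata,c05,LV,P
027,Oleata,c06,LV,D
028,Cerina,c06,LV,D
029,Gelata,c06,LV,D
030,Gelata,c06,LV,D
031,Olia,c02,LV,D
032,Casciola,c02,LV,P
033,Panaia,c02,LV,D
034,Panaia,c02,LV,P
035,Pagliaccia,c02,LV,P
036,Casciola,c02,LV,P
037,Casciola,c02,LV,D
038,Sonaja Rossa,c07,LV,D
039,Ciocarina Bianca,c07,LV,D
040,Ciocarina Rossa Dossa,c07,LV,D
041,Ciochera Rosa,c07,LV,D
042,Pum Giuan,c08,CV,D
043,San Giovanni PT,c08,LV,D
044,San Giovanni MO,c08,LV,P
045,San Giovanni BO,c08,LV,P
046,Ceres,c08,LV,D
047,Golden Delicious,c02,CV,D
048,Golden Gala,c02,CV,D
049,Amerina,c02,LV,D
050,Pianella,c02,LV,P
051,Unknown,c02,UA,D
052,Appiola Rossa,c02,LV,D
053,Rosa D'Amelia,c02,LV,D
054,Unknown,c02,UA,P
055,Unknown,c02,UA,D
056,Unknown,c02,UA,P
057,Bianchina,c02,LV,D
058,Coccianese,c02,LV,D
059,Coccianese,c02,LV,D
060,Unknown,c02,UA,D
061,Limoncella,c02,LV,D
062,Piattuccia,c02,LV,D
063,Stratarina,c02,LV,D
064,Conventina,c02,LV,D
065,Muso di Bue,c02,LV,D
066,Ruzza,c02,LV,D
067,Spoletina,c02,LV,P
068,Unknown,c02,UA,D
069,Unknown,c02,UA,P
070,Rossa Doglio,c02,LV,D
071,Gialla Doglio,c02,LV,D
072,Ciucca Dolcetta,c02,LV,D
073,Polsola,c02,LV,P
074,Dolcetta,c02,LV,D
075,Unknown,c02,UA,D
076,Unknown,c02,UA,D
077,Appiola Rossa,c02,LV,P
078,Appiola,c02,LV,D
079,Unknown,c02,UA,D
080,Ducale,c02,LV,D
081,Pianella,c02,LV,D
082,Rosciola,c02,LV,D
083,Unknown,c02,UA,P
084,Unknown,c02,UA,D
085,Unknown,c02,UA,D
086,Ulpia,c02,LV,D
087,Amerina,c02,LV,D
088,Saragano Rossa,c02,LV,D
089,Unknown,c02,UA,D
090,Unknown,c02,UA,D
091,Saragano Gialla,c02,LV,D
092,Unknown,c02,UA,D
093,Unknown,c02,UA,P
094,Unknown,c02,UA,D
095,Unknown,c02,UA,D
096,Unknown,c02,UA,D
097,Unknown,c02,UA,D
098,Unknown,c02,UA,D
099,Unknown,c02,UA,P
100,Unknown,c02,UA,D
101,Maggiolina,c02,LV,D
102,Unknown,c02,UA,P
103,Unknown,c02,UA,D
104,Rossa Montelupone,c02,LV,D
105,Unknown,c02,UA,D
106,Unknown,c02,UA,D
107,Gialla Montelupone,c02,LV,D
108,Unknown,c02,UA,D
109,Unknown,c02,UA,P
110,Unknown,c02,UA,D
111,Unknown,c02,UA,D
112,Paradisa,c02,LV,D
113,Unknown,c02,UA,D
114,Unknown,c02,UA,P
115,Coppiola,c02,LV,D
116,Unknown,c02,UA,P
117,Unknown,c02,UA,D
118,Rosa in Pietra,c03,LV,D
119,Del Castagno,c03,LV,D
120,Ciucca,c03,LV,D
121,Rosa Gentile,c03,LV,D
122,Rosa Romana,c03,LV,P
123,Polsola,c03,LV,D
124,Bianchina,c03,LV,P
125,Unknown,c03,UA,D
126,Limoncella,c03,LV,D
127,Conventina,c03,LV,D
128,Roggia,c03,LV,D
129,Durello,c09,LV,D
130,Calvilla d'Estate,c09,CV,D
131,Reinette du Canada,c09,CV,P
132,Reinette Ananas,c09,CV,D
133,Reinette de Champagne,c09,CV,D
134,Limoncina,c09,CV,D
135,Decio,c09,LV,D
136,Annurca,c09,CV,D
137,Abbondanza,c09,CV,D
138,Unknown,c02,UA,D
139,Spoletina,c02,LV,P
140,Unknown,c02,UA,P
141,Limoncella,c02,LV,D
142,Unknown,c02,UA,D
143,Unknown,c02,UA,D
144,Unknown,c02,UA,D
145,Unknown,c02,UA,P
146,Gelata,c02,LV,D
147,Rosa in Pietra,c02,LV,D
148,Unknown,c02,UA,D
149,Coccianese,c02,LV,D
150,Unknown,c02,UA,D
151,Unknown,c02,UA,D
152,Cera,c02,LV,D
153,Unknown,c02,UA,D
154,Unknown,c02,UA,D
155,Unknown,c02,UA,D
156,Statia,c02,LV,D
157,Unknown,c02,UA,D
158,Paonazza di Piubbica,c02,LV,D
159,Annurca,c02,CV,D
160,Unknown,c02,UA,D
161,Unknown,c02,UA,P
162,Unknown,c02,UA,P
163,Unknown,c02,UA,P
164,Unknown,c02,UA,D
165,Rossa di San Venanzo,c02,CV,D
166,Unknown,c02,UA,D
167,Unknown,c02,UA,D
168,Unknown,c02,UA,D
169,Rosona,c02,LV,P
170,Golden Clone B,c10,CV,D
171,Fuji,c10,CV,D
172,Stark Delicious,c10,CV,D
173,Unknown,c10,UA,D
174,Gold Chief (Gold Pink),c10,CV,D
175,Cripps Pink,c10,CV,D
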